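"""Study-design arithmetic for the marker-based capture validation cohort.

The quality-control benchmark this package is calibrated against records a
cohort of mice carrying ten implanted markers during one-minute open-field
trials at 300 fps, with paired markers at known spacing (hip pairs 14 mm
apart; the lower-leg marker sits 14 mm above the heel and 14 mm below the
upper-leg marker).  These helpers express the design's headline arithmetic —
dataset size, marker payload relative to body mass, and the projection of the
isotropic 3D triangulation residual onto a 2D imaging plane — so reports can
derive them instead of hard-coding magic numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

from .motion_index import project_residual_to_2d

__all__ = ["StudyDesign", "DEFAULT_DESIGN"]


@dataclass(frozen=True)
class StudyDesign:
    n_mice: int = 10
    n_trials_per_mouse: int = 3
    n_markers: int = 10
    trial_duration_s: float = 60.0
    frame_rate: float = 300.0
    markerhead_total_mass_g: float = 3.0  # retroreflective heads, all ten
    mouse_mass_g: float = 25.0
    mean_residual_3d_mm: float = 0.35
    heel_to_lower_marker_mm: float = 14.0
    lower_to_upper_marker_mm: float = 14.0

    @property
    def frames_per_trial(self) -> int:
        return int(round(self.trial_duration_s * self.frame_rate))

    def dataset_sample_count(self) -> int:
        """Marker samples across the cohort: mice x trials x markers x frames."""
        return (
            self.n_mice * self.n_trials_per_mouse * self.n_markers * self.frames_per_trial
        )

    def marker_payload_pct(self) -> float:
        """Worn marker mass as a percentage of body mass."""
        return 100.0 * self.markerhead_total_mass_g / self.mouse_mass_g

    def noise_floor_2d_mm(self) -> float:
        """2D projection of the mean isotropic 3D triangulation residual."""
        return project_residual_to_2d(self.mean_residual_3d_mm)

    def heel_to_upper_leg_mm(self) -> float:
        return self.heel_to_lower_marker_mm + self.lower_to_upper_marker_mm


DEFAULT_DESIGN = StudyDesign()
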