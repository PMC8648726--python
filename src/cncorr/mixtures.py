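"""Signature subcellular activities and phase-specific activity mixtures.

Single-fibroblast locomotion decomposes into a small set of subcellular
events, each leaving a characteristic polar angle in the CN plot (the
scatter of cell-centroid displacement CCD against the nuclear displacement
projected on the CCD direction, NCD_par).  The six signature activities and
their canonical peak angles are:

======================================  ============
activity                                peak angle
======================================  ============
nucleus-forward movement                ~ 25 deg
trailing-edge detachment                ~ 45 deg
simultaneous detachment-protrusion      ~ 65 deg
leading-edge protrusion                 ~ 90 deg
side protrusion                         ~ 115 deg
leading-edge retraction                 ~ 145 deg
======================================  ============

A cell-cycle phase is characterized by a finite mixture of these
activities; :data:`PHASE_MIXTURES` holds the published per-phase peak
angles and weights for synchronized NIH 3T3 fibroblasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SIGNATURE_ANGLES",
    "SIGNATURE_LABELS",
    "ActivityComponent",
    "ActivityMixture",
    "PHASE_MIXTURES",
    "PHASES",
]

#: canonical signature polar angles (degrees), keyed by activity label
SIGNATURE_ANGLES: dict[str, float] = {
    "nucleus_forward": 25.0,
    "trailing_edge_detachment": 45.0,
    "simultaneous_de_pro": 65.0,
    "leading_edge_protrusion": 90.0,
    "side_protrusion": 115.0,
    "leading_edge_retraction": 145.0,
}

SIGNATURE_LABELS: tuple[str, ...] = tuple(SIGNATURE_ANGLES)

#: default angular spread of a single activity's CN polar-angle distribution
DEFAULT_SD_DEG = 8.0


@dataclass(frozen=True)
class ActivityComponent:
    """One activity in a mixture: a normal polar-angle peak with a weight."""

    label: str
    mean_angle: float  # degrees in [0, 180]
    sd_angle: float = DEFAULT_SD_DEG  # degrees, > 0
    weight: float = 1.0  # mixture fraction

    def __post_init__(self) -> None:
        if self.label not in SIGNATURE_ANGLES:
            raise ValueError(
                f"unknown activity label {self.label!r}; "
                f"expected one of {SIGNATURE_LABELS}"
            )
        if not 0.0 <= self.mean_angle <= 180.0:
            raise ValueError("mean_angle must lie in [0, 180] degrees")
        if self.sd_angle <= 0:
            raise ValueError("sd_angle must be positive")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")


@dataclass(frozen=True)
class ActivityMixture:
    """A finite mixture of signature activities for one condition/phase.

    Parameters
    ----------
    components :
        Activity components with strictly increasing mean angles.  Weights
        are normalized to sum to one at construction.
    ccd_median :
        Median of the log-normal per-step CCD magnitude (µm per frame
        interval) shared by all activities of the mixture.
    ccd_sigma_log :
        Log-scale sigma of the CCD magnitude distribution.
    name :
        Optional condition name (e.g. a cell-cycle phase).
    """

    components: tuple[ActivityComponent, ...]
    ccd_median: float = 0.5
    ccd_sigma_log: float = 0.4
    name: str = ""

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("mixture needs at least one component")
        means = [c.mean_angle for c in self.components]
        if any(b <= a for a, b in zip(means, means[1:])):
            raise ValueError("component mean angles must be strictly increasing")
        total = float(sum(c.weight for c in self.components))
        if total <= 0:
            raise ValueError("total weight must be positive")
        if abs(total - 1.0) > 1e-9:
            normed = tuple(
                ActivityComponent(c.label, c.mean_angle, c.sd_angle, c.weight / total)
                for c in self.components
            )
            object.__setattr__(self, "components", normed)
        if self.ccd_median <= 0:
            raise ValueError("ccd_median must be positive")

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    @property
    def mean_angles(self) -> np.ndarray:
        return np.array([c.mean_angle for c in self.components])

    @property
    def sd_angles(self) -> np.ndarray:
        return np.array([c.sd_angle for c in self.components])

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.components)


def _mix(name, ccd_median, *comps):
    return ActivityMixture(
        components=tuple(ActivityComponent(lbl, ang, DEFAULT_SD_DEG, w / 100.0)
                         for lbl, ang, w in comps),
        ccd_median=ccd_median,
        name=name,
    )


#: published per-phase activity mixtures for synchronized NIH 3T3
#: fibroblasts: (label, peak angle deg, weight %).  Phases whose printed
#: percentages sum to 99 are renormalized at construction.
PHASE_MIXTURES: dict[str, ActivityMixture] = {
    "earlyG1": _mix(
        "earlyG1", 0.6,
        ("trailing_edge_detachment", 45.0, 32.0),
        ("leading_edge_protrusion", 80.0, 60.0),
        ("leading_edge_retraction", 144.0, 8.0),
    ),
    "lateG1": _mix(
        "lateG1", 0.5,
        ("trailing_edge_detachment", 41.0, 29.0),
        ("leading_edge_protrusion", 85.0, 59.0),
        ("side_protrusion", 132.0, 5.0),
        ("leading_edge_retraction", 158.0, 6.0),
    ),
    "S": _mix(
        "S", 0.3,
        ("nucleus_forward", 18.0, 4.0),
        ("trailing_edge_detachment", 41.0, 16.0),
        ("leading_edge_protrusion", 81.0, 70.0),
        ("leading_edge_retraction", 144.0, 9.0),
    ),
    "G2": _mix(
        "G2", 0.5,
        ("nucleus_forward", 29.0, 8.0),
        ("simultaneous_de_pro", 67.0, 52.0),
        ("leading_edge_protrusion", 88.0, 16.0),
        ("side_protrusion", 110.0, 20.0),
        ("leading_edge_retraction", 158.0, 4.0),
    ),
}

PHASES: tuple[str, ...] = tuple(PHASE_MIXTURES)
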