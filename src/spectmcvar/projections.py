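"""Energy windows and projection-data containers."""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class EnergyWindow:
    lower: float  # keV
    upper: float  # keV
    role: str  # lower_scatter | photopeak | upper_scatter

    def __post_init__(self):
        if self.upper <= self.lower:
            raise ValueError("window upper bound must exceed lower bound")

    @property
    def width(self) -> float:
        return self.upper - self.lower


def lu177_tew_windows() -> list[EnergyWindow]:
    """The triple-energy-window set bracketing the 208 keV line.

    Order is (photopeak, lower scatter, upper scatter); the photopeak
    always comes first so that window index 0 is the reconstruction target.
    """
    return [
        EnergyWindow(187.2, 228.8, "photopeak"),
        EnergyWindow(166.4, 187.2, "lower_scatter"),
        EnergyWindow(228.8, 249.6, "upper_scatter"),
    ]


@dataclass
class ProjectionSet:
    """Per-energy-window stacks of detector count maps.

    ``counts`` has shape (n_windows, n_angles, nu, nv) where (nu, nv)
    index the transaxial and axial detector pixels. ``provenance``
    optionally carries the primary/scatter split of the photopeak window
    and the scatter-order weight histogram.
    """

    counts: np.ndarray
    geom: "AcqGeometry"
    windows: list[EnergyWindow]
    noise_state: str = "expected"  # expected | poisson_sampled
    provenance: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if not self.windows:
            raise ValueError("window list must be nonempty")
        if self.counts.shape[0] != len(self.windows):
            raise ValueError("counts leading axis must match number of windows")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    def window(self, role: str) -> np.ndarray:
        for i, w in enumerate(self.windows):
            if w.role == role:
                return self.counts[i]
        raise KeyError(f"no window with role {role!r}")

    def has_window(self, role: str) -> bool:
        return any(w.role == role for w in self.windows)

    @property
    def photopeak(self) -> np.ndarray:
        return self.window("photopeak")

    def save(self, path: str | Path):
        """Write the stack plus a JSON sidecar with geometry and provenance."""
        path = Path(path)
        np.savez_compressed(
            path.with_suffix(".npz"),
            counts=self.counts,
            **{f"prov_{k}": v for k, v in self.provenance.items()
               if isinstance(v, np.ndarray)},
        )
        sidecar = {
            "windows": [
                {"lower": w.lower, "upper": w.upper, "role": w.role}
                for w in self.windows
            ],
            "noise_state": self.noise_state,
            "angles_deg": list(np.asarray(self.geom.angles, dtype=float)),
            "radius_of_rotation_mm": self.geom.radius_of_rotation,
            "detector_pixel_mm": list(self.geom.detector_pixel),
            "time_per_projection_s": self.geom.time_per_projection,
            "meta": {k: v for k, v in self.meta.items()
                     if isinstance(v, (int, float, str, bool, list))},
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
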