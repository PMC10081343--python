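"""Synthetic anthropomorphic activity/attenuation phantoms.

A parameterised stand-in for an anthropomorphic torso slice: an elliptical
body of soft tissue, two low-attenuation lung-like regions, a higher
attenuation spine-like disk, several hot activity lesions and a central
cold spot.  Both maps are piecewise constant (gradient sparse), which is
the regime the TV-constrained reconstruction targets.  The activity map is
normalised so its maximum is 1.0; attenuation is in cm^-1 with soft tissue
inside the conventional 511 keV display window [0.075, 0.115].

Rasterisation assigns a feature's value to every pixel whose centre lies
inside the feature; later-listed features overwrite earlier ones.
Generation is deterministic given the spec.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Feature",
    "PhantomSpec",
    "default_features",
    "make_phantom",
    "truncate_activity",
]


@dataclass(frozen=True)
class Feature:
    """One elliptical/circular phantom feature.

    ``activity`` / ``attenuation`` of None leave the corresponding map
    untouched inside the feature (e.g. a hot lesion that keeps the body's
    attenuation).
    """

    shape: str  # "disk" or "ellipse"
    center_cm: tuple[float, float]
    radii_cm: tuple[float, float]
    activity: float | None = None
    attenuation: float | None = None

    def __post_init__(self) -> None:
        if self.shape not in ("disk", "ellipse"):
            raise ValueError(f"unknown feature shape {self.shape!r}")
        if min(self.radii_cm) <= 0:
            raise ValueError("feature radii must be positive")
        if self.activity is not None and self.activity < 0:
            raise ValueError("activity values must be nonnegative")
        if self.attenuation is not None and self.attenuation < 0:
            raise ValueError("attenuation values must be nonnegative")


def default_features(body_attenuation: float = 0.096) -> tuple[Feature, ...]:
    """Torso-like feature list: body, lungs, spine, hot lesions, cold spot.

    Sizes are in cm on a 30 cm FOV.  Soft tissue sits at
    ``body_attenuation``; lungs are low attenuation, the spine-like disk is
    at the top of the soft-tissue display window.
    """
    return (
        Feature("ellipse", (0.0, 0.0), (12.0, 9.0), activity=0.4,
                attenuation=body_attenuation),
        Feature("ellipse", (-5.2, 2.0), (3.4, 2.6), activity=0.12, attenuation=0.035),
        Feature("ellipse", (5.2, 2.0), (3.4, 2.6), activity=0.12, attenuation=0.035),
        Feature("disk", (0.0, -6.3), (1.8, 1.8), activity=0.1, attenuation=0.115),
        Feature("disk", (4.5, -3.2), (1.4, 1.4), activity=1.0),
        Feature("disk", (-4.3, -3.4), (1.2, 1.2), activity=0.85),
        Feature("disk", (0.0, 5.6), (1.1, 1.1), activity=0.9),
        Feature("disk", (0.0, -0.5), (1.6, 1.6), activity=0.0),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a phantom pair on a common grid."""

    grid_n: int = 176
    fov_cm: float = 30.0
    body_attenuation: float = 0.096
    features: tuple[Feature, ...] | None = None
    truncation_radius_cm: float | None = None

    def __post_init__(self) -> None:
        if self.grid_n < 16:
            raise ValueError("grid_n must be at least 16")
        if self.fov_cm <= 0:
            raise ValueError("fov_cm must be positive")
        if self.body_attenuation < 0:
            raise ValueError("body_attenuation must be nonnegative")
        if self.features is None:
            object.__setattr__(
                self, "features", default_features(self.body_attenuation)
            )

    def with_truncation(self, radius_cm: float) -> "PhantomSpec":
        return replace(self, truncation_radius_cm=radius_cm)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "features" in d and d["features"] is not None:
            d["features"] = tuple(
                Feature(
                    shape=f["shape"],
                    center_cm=tuple(f["center_cm"]),
                    radii_cm=tuple(f["radii_cm"]),
                    activity=f.get("activity"),
                    attenuation=f.get("attenuation"),
                )
                for f in d["features"]
            )
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        d = {
            "grid_n": self.grid_n,
            "fov_cm": self.fov_cm,
            "body_attenuation": self.body_attenuation,
            "truncation_radius_cm": self.truncation_radius_cm,
            "features": [
                {
                    "shape": f.shape,
                    "center_cm": list(f.center_cm),
                    "radii_cm": list(f.radii_cm),
                    "activity": f.activity,
                    "attenuation": f.attenuation,
                }
                for f in self.features
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _pixel_centers(grid_n: int, fov_cm: float):
    h = fov_cm / grid_n
    c = -fov_cm / 2.0 + (np.arange(grid_n) + 0.5) * h
    # row index (first axis) increases with +y
    return np.meshgrid(c, c, indexing="xy")


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Rasterise a spec into (activity, attenuation) images.

    Returns two ``(grid_n, grid_n)`` float arrays on the same grid.  The
    activity map is rescaled so its maximum equals 1.0 (unless it is
    identically zero).  Raises ValueError if the rasterised activity
    support escapes the attenuation support (a physically contradictory
    feature overlap).
    """
    X, Y = _pixel_centers(spec.grid_n, spec.fov_cm)
    act = np.zeros_like(X)
    att = np.zeros_like(X)
    for f in spec.features:
        rx, ry = f.radii_cm
        inside = ((X - f.center_cm[0]) / rx) ** 2 + ((Y - f.center_cm[1]) / ry) ** 2 <= 1.0
        if f.activity is not None:
            act[inside] = f.activity
        if f.attenuation is not None:
            att[inside] = f.attenuation
    if act.max() > 0:
        act /= act.max()
    if np.any((act > 0) & (att == 0)):
        raise ValueError(
            "contradictory features: activity support escapes the attenuation support"
        )
    if spec.truncation_radius_cm is not None:
        act = truncate_activity(act, spec.truncation_radius_cm, spec.fov_cm)
    return act, att


def truncate_activity(
    activity: np.ndarray, radius_cm: float, fov_cm: float
) -> np.ndarray:
    """Zero the activity outside a centred circle; inside it is unchanged."""
    if radius_cm <= 0:
        raise ValueError("truncation radius must be positive")
    n = activity.shape[0]
    X, Y = _pixel_centers(n, fov_cm)
    out = activity.copy()
    out[X**2 + Y**2 > radius_cm**2] = 0.0
    return out
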