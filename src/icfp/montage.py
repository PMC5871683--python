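"""Electrode montage geometry in topographic polar coordinates.

Scalp positions are described by an angle ``theta`` measured in degrees from
the nasion-inion midline (negative values on the left hemisphere) and a
normalized ``radius`` (0 at the vertex, 1.0 at the outermost electrode ring).
The spatial fingerprint features contrast average IC weights over four
angular/radial regions of this disc:

* FA — frontal area, ``|theta| <= 60`` and ``radius >= 0.4``;
* PA — posterior area, ``|theta| <= 120`` restricted to the outer
  electrode ring (the radial constraint is what makes it posterior-ish on
  real caps, where the outer ring is dominated by temporal/occipital sites);
* LE / RE — left and right fronto-temporal areas, ``theta`` in
  ``[-60, -30]`` and ``[30, 60]`` respectively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ElectrodeMontage",
    "EmptyRegionError",
    "select_region",
    "frontal_area",
    "posterior_area",
    "left_eye_area",
    "right_eye_area",
    "make_quasi_equidistant_montage",
    "builtin_montages",
    "read_montage",
    "write_montage",
]

#: tolerance below the outer ring still counted as "outer ring"
OUTER_RING_EPS = 0.05


class EmptyRegionError(ValueError):
    """Raised when a scalp region query matches no electrode.

    Spatial features catch this and degrade to a value of 0 with a warning,
    so sparse montages never abort a feature table.
    """


@dataclass(frozen=True)
class ElectrodeMontage:
    """Electrode labels with topographic polar scalp coordinates.

    Parameters
    ----------
    labels
        Unique electrode names, one per channel.
    theta
        Signed angle in degrees from the nasion midline axis, in
        ``[-180, 180]``; negative on the left hemisphere.
    radius
        Normalized radial position, 0 at the vertex, 1.0 on the outermost
        electrode ring.
    """

    labels: tuple[str, ...]
    theta: np.ndarray = field(repr=False)
    radius: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        radius = np.asarray(self.radius, dtype=float)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "radius", radius)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("electrode labels must be unique")
        if not (len(self.labels) == theta.size == radius.size):
            raise ValueError("labels, theta and radius must have equal length")
        if theta.size == 0:
            raise ValueError("montage must contain at least one electrode")
        if np.any(np.abs(theta) > 180):
            raise ValueError("theta must lie in [-180, 180] degrees")
        if np.any(radius < 0):
            raise ValueError("radius must be non-negative")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def subset(self, keep: np.ndarray) -> "ElectrodeMontage":
        """Montage restricted to the given index array (order preserved)."""
        keep = np.asarray(keep, dtype=int)
        return ElectrodeMontage(
            labels=tuple(self.labels[i] for i in keep),
            theta=self.theta[keep],
            radius=self.radius[keep],
        )


def select_region(
    montage: ElectrodeMontage,
    angle_lo: float,
    angle_hi: float,
    radius_lo: float = 0.0,
    radius_hi: float = np.inf,
    mirror: bool = True,
) -> np.ndarray:
    """Indices of electrodes inside a closed angular/radial sector.

    With ``mirror`` set the test is on ``|theta|`` so the sector covers both
    hemispheres; otherwise signed theta is used (negative = left).  All
    interval bounds are inclusive.  Raises :class:`EmptyRegionError` when no
    electrode falls inside, so callers can degrade gracefully.
    """
    if angle_lo > angle_hi:
        raise ValueError("angle_lo must not exceed angle_hi")
    if not (0 <= radius_lo <= radius_hi):
        raise ValueError("need 0 <= radius_lo <= radius_hi")
    ang = np.abs(montage.theta) if mirror else montage.theta
    mask = (
        (ang >= angle_lo)
        & (ang <= angle_hi)
        & (montage.radius >= radius_lo)
        & (montage.radius <= radius_hi)
    )
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise EmptyRegionError(
            f"no electrode in region theta[{angle_lo},{angle_hi}] "
            f"radius[{radius_lo},{radius_hi}] (mirror={mirror})"
        )
    return idx


def frontal_area(montage: ElectrodeMontage) -> np.ndarray:
    """FA: ``|theta| <= 60`` degrees from nasion, ``radius >= 0.4``."""
    return select_region(montage, 0.0, 60.0, radius_lo=0.4, mirror=True)


def posterior_area(
    montage: ElectrodeMontage, outer_ring_eps: float = OUTER_RING_EPS
) -> np.ndarray:
    """PA: ``|theta| <= 120`` degrees, on the outer electrode ring.

    "Outer ring" is taken as radius within ``outer_ring_eps`` of the montage
    maximum, since exact radius equality is brittle on real caps.  The
    angular range is interpreted literally; the radial constraint is what
    excludes central/frontal sites.
    """
    r_max = float(montage.radius.max())
    return select_region(
        montage,
        0.0,
        120.0,
        radius_lo=max(0.0, r_max - outer_ring_eps),
        radius_hi=r_max,
        mirror=True,
    )


def left_eye_area(montage: ElectrodeMontage) -> np.ndarray:
    """LE: left fronto-temporal area, theta in ``[-60, -30]`` degrees."""
    return select_region(montage, -60.0, -30.0, mirror=False)


def right_eye_area(montage: ElectrodeMontage) -> np.ndarray:
    """RE: right fronto-temporal area, theta in ``[30, 60]`` degrees."""
    return select_region(montage, 30.0, 60.0, mirror=False)


def make_quasi_equidistant_montage(n_electrodes: int) -> ElectrodeMontage:
    """Deterministic quasi-equidistant synthetic montage of ``n`` electrodes.

    Electrodes are placed on a sunflower (golden-angle) spiral over the scalp
    disc, then rotated so the layout is left/right symmetric enough that the
    FA/PA/LE/RE regions resolve for ``n >= 4``.  The same ``n`` always yields
    the same coordinates.
    """
    if n_electrodes < 1:
        raise ValueError("n_electrodes must be >= 1")
    k = np.arange(n_electrodes)
    # sunflower spiral: radius grows as sqrt, angle by the golden angle
    golden = 180.0 * (3.0 - np.sqrt(5.0))
    radius = np.sqrt((k + 0.5) / n_electrodes)
    radius = radius / radius.max() if n_electrodes > 1 else np.ones(1)
    theta = np.mod(k * golden, 360.0)
    theta = np.where(theta > 180.0, theta - 360.0, theta)
    if n_electrodes >= 4:
        # pin four anchors so every spatial region is non-empty even at n=4
        theta[:4] = [0.0, 120.0, -45.0, 45.0]
        radius[:4] = [0.8, 1.0, 0.7, 0.7]
    labels = tuple(f"E{i + 1}" for i in range(n_electrodes))
    return ElectrodeMontage(labels=labels, theta=theta, radius=radius)


def builtin_montages() -> dict[str, ElectrodeMontage]:
    """Named synthetic montages at common cap sizes (21/32/64/97/128)."""
    return {
        f"quasi{n}": make_quasi_equidistant_montage(n) for n in (21, 32, 64, 97, 128)
    }


def read_montage(path) -> ElectrodeMontage:
    """Read a montage from a delimited text file.

    Expected columns: ``label``, ``theta``, ``radius`` (tab- or
    comma-separated, header required).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"label", "theta", "radius"} - set(df.columns)
    if missing:
        raise ValueError(f"montage file missing columns: {sorted(missing)}")
    return ElectrodeMontage(
        labels=tuple(df["label"].astype(str)),
        theta=df["theta"].to_numpy(float),
        radius=df["radius"].to_numpy(float),
    )


def write_montage(montage: ElectrodeMontage, path) -> None:
    pd.DataFrame(
        {"label": montage.labels, "theta": montage.theta, "radius": montage.radius}
    ).to_csv(path, sep="\t", index=False)


def region_indices(
    montage: ElectrodeMontage, warn: bool = True
) -> dict[str, np.ndarray]:
    """All four spatial-feature regions; empty regions become empty arrays.

    Used by the spatial features, which must degrade to 0 (not crash) on
    montages lacking a region.
    """
    out: dict[str, np.ndarray] = {}
    for name, fn in (
        ("FA", frontal_area),
        ("PA", posterior_area),
        ("LE", left_eye_area),
        ("RE", right_eye_area),
    ):
        try:
            out[name] = fn(montage)
        except EmptyRegionError:
            if warn:
                warnings.warn(
                    f"montage has no electrodes in region {name}; "
                    "dependent spatial features will be 0",
                    stacklevel=2,
                )
            out[name] = np.empty(0, dtype=int)
    return out
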