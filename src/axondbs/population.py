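"""Randomized population of parallel fibers around the stimulating electrode.

Fibers run parallel to the x axis; the point source sits at the origin with
the electrode shaft extending along +z. A fiber's pose is the position of
its axis in the (y, z) cross-sectional plane plus a longitudinal offset of
its node lattice. Axis positions are sampled uniformly over the disk of
radius 3 mm, excluding (a) the 0.635 mm sphere around the source and (b)
the shaft keep-out: the semi-infinite cylinder of radius 0.635 mm above the
source (z > 0, |y| < 0.635), which together give the U-shaped allowed
region around a DBS lead of 1.27 mm diameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fiber import FiberGeometry

__all__ = [
    "EXCLUSION_RADIUS_MM",
    "MAX_RADIUS_MM",
    "FiberPose",
    "PopulationLayout",
    "pose_allowed",
    "sample_population",
    "fiber_distance_profile",
]

EXCLUSION_RADIUS_MM = 0.635
MAX_RADIUS_MM = 3.0


@dataclass(frozen=True)
class FiberPose:
    """Placement of one fiber relative to the source.

    ``radial_distance_mm`` is the perpendicular distance from the source to
    the fiber axis, ``azimuth_rad`` the angle of the axis position in the
    (y, z) plane (z = r*sin(azimuth) points along the electrode shaft), and
    ``longitudinal_offset_um`` shifts the node lattice along the axis,
    within +-1/2 internodal spacing.
    """

    radial_distance_mm: float
    azimuth_rad: float
    longitudinal_offset_um: float

    @property
    def y_mm(self) -> float:
        return self.radial_distance_mm * np.cos(self.azimuth_rad)

    @property
    def z_mm(self) -> float:
        return self.radial_distance_mm * np.sin(self.azimuth_rad)


@dataclass
class PopulationLayout:
    n_fibers: int
    poses: list[FiberPose]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fiber": np.arange(self.n_fibers),
            "radial_mm": [p.radial_distance_mm for p in self.poses],
            "azimuth_rad": [p.azimuth_rad for p in self.poses],
            "offset_um": [p.longitudinal_offset_um for p in self.poses],
            "seed": self.seed,
        })

    def save(self, path: str | Path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "PopulationLayout":
        df = pd.read_csv(path)
        poses = [FiberPose(r, a, o) for r, a, o in
                 zip(df["radial_mm"], df["azimuth_rad"], df["offset_um"])]
        return cls(len(poses), poses, int(df["seed"].iloc[0]))


def pose_allowed(y_mm: float, z_mm: float,
                 r_max: float = MAX_RADIUS_MM,
                 r_excl: float = EXCLUSION_RADIUS_MM) -> bool:
    """True if a fiber axis through (y, z) respects both exclusion rules."""
    r = float(np.hypot(y_mm, z_mm))
    if r > r_max or r < r_excl:
        return False
    if z_mm > 0 and abs(y_mm) < r_excl:  # electrode shaft keep-out
        return False
    return True


def sample_population(n_fibers: int, seed: int, geom: FiberGeometry,
                      r_max: float = MAX_RADIUS_MM,
                      r_excl: float = EXCLUSION_RADIUS_MM,
                      max_attempts: int = 10000) -> PopulationLayout:
    """Rejection-sample fiber poses uniformly over the allowed region."""
    if n_fibers < 1:
        raise ValueError("n_fibers must be >= 1")
    rng = np.random.default_rng(seed)
    half = geom.internode_spacing_um / 2.0
    poses: list[FiberPose] = []
    for _ in range(n_fibers):
        for attempt in range(max_attempts):
            y, z = rng.uniform(-r_max, r_max, size=2)
            if pose_allowed(y, z, r_max, r_excl):
                break
        else:
            raise RuntimeError("rejection sampling failed to find a pose")
        poses.append(FiberPose(
            radial_distance_mm=float(np.hypot(y, z)),
            azimuth_rad=float(np.arctan2(z, y)),
            longitudinal_offset_um=float(rng.uniform(-half, half)),
        ))
    return PopulationLayout(n_fibers, poses, seed)


def fiber_distance_profile(pose: FiberPose, geom: FiberGeometry) -> np.ndarray:
    """Source-to-compartment-center distance (mm) for every compartment.

    The node indexed ``geom.electrode_node_index`` is aligned with the
    source along the axis, then shifted by the pose's longitudinal offset:
    r_c = sqrt(radial^2 + axial^2).
    """
    e_node = geom.node_compartments[geom.electrode_node_index]
    axial_um = (geom.position_um - geom.position_um[e_node]
                + pose.longitudinal_offset_um)
    axial_mm = axial_um * 1e-3
    return np.hypot(pose.radial_distance_mm, axial_mm)
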