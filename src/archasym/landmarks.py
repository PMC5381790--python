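"""Landmark data model: schemes, configurations and aligned sets.

A *configuration* is one digitisation of one side of one individual's
pharyngeal arch: an ``n_points x dims`` coordinate matrix plus metadata.
A *scheme* records which points are fixed (Type-2) landmarks and which
belong to sliding semi-landmark chains anchored at fixed landmarks.

All indices at the public interface are 1-based, matching the numbering
used when digitising; arrays are stored 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Chain",
    "LandmarkScheme",
    "Configuration",
    "ConfigurationSet",
    "AlignedSet",
    "default_scheme",
    "plain_scheme",
]


@dataclass(frozen=True)
class Chain:
    """A semi-landmark chain: ``start`` and ``end`` anchors (fixed landmarks)
    delimiting an ordered run of sliding semi-landmarks.  1-based indices."""

    start: int
    semis: tuple[int, ...]
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "semis", tuple(int(i) for i in self.semis))
        if len(self.semis) < 1:
            raise ValueError("a chain needs at least one semi-landmark")


@dataclass(frozen=True)
class LandmarkScheme:
    """Bookkeeping for fixed landmarks and semi-landmark chains.

    Parameters
    ----------
    n_points
        Points per side (fixed landmarks + semi-landmarks).
    dims
        Spatial dimension (2 or 3).
    fixed
        1-based indices of the fixed landmarks.
    chains
        Semi-landmark chains; chain anchors must be fixed landmarks and
        fixed / semi-landmark indices must jointly cover ``1..n_points``.
    """

    n_points: int = 33
    dims: int = 3
    fixed: tuple[int, ...] = (1, 2, 3, 4, 18, 19, 33)
    chains: tuple[Chain, ...] = (
        Chain(4, tuple(range(5, 18)), 18),
        Chain(19, tuple(range(20, 33)), 33),
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed", tuple(int(i) for i in self.fixed))
        object.__setattr__(self, "chains", tuple(self.chains))
        fixed = set(self.fixed)
        semis: list[int] = []
        for c in self.chains:
            if c.start not in fixed or c.end not in fixed:
                raise ValueError(f"chain anchors ({c.start}, {c.end}) must be fixed landmarks")
            semis.extend(c.semis)
        semi_set = set(semis)
        if len(semi_set) != len(semis):
            raise ValueError("semi-landmark indices repeat across chains")
        if fixed & semi_set:
            raise ValueError("fixed and semi-landmark indices overlap")
        all_idx = fixed | semi_set
        if all_idx != set(range(1, self.n_points + 1)):
            raise ValueError(
                "fixed landmarks and chains must jointly cover 1..n_points "
                f"(got {sorted(all_idx)} for n_points={self.n_points})"
            )
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")

    @property
    def semilandmarks(self) -> tuple[int, ...]:
        """All semi-landmark indices in chain order (1-based)."""
        out: list[int] = []
        for c in self.chains:
            out.extend(c.semis)
        return tuple(out)

    @property
    def n_semilandmarks(self) -> int:
        return len(self.semilandmarks)


def default_scheme() -> LandmarkScheme:
    """The 33-point 3D pharyngeal-arch scheme: 7 fixed landmarks and two
    13-point semi-landmark chains (outer ridge 4-[5..17]-18, inner curve
    19-[20..32]-33)."""
    return LandmarkScheme()


def plain_scheme(n_points: int, dims: int = 3) -> LandmarkScheme:
    """A scheme of fixed landmarks only (no sliding)."""
    return LandmarkScheme(
        n_points=n_points, dims=dims, fixed=tuple(range(1, n_points + 1)), chains=()
    )


@dataclass(frozen=True)
class Configuration:
    """A single landmark configuration with its metadata."""

    coords: np.ndarray
    individual: str
    side: str = "L"
    replicate: int = 1
    biotype: str | None = None
    lineage: str | None = None
    site: str | None = None
    formula: str | None = None
    reflected: bool = False

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2:
            raise ValueError("coords must be an n_points x dims matrix")
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"non-finite coordinates in configuration {self.key}")
        coords.setflags(write=False)
        object.__setattr__(self, "coords", coords)
        if self.side not in ("L", "R"):
            raise ValueError(f"side must be 'L' or 'R', got {self.side!r}")

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.individual, self.side, self.replicate)

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    @property
    def dims(self) -> int:
        return self.coords.shape[1]

    def with_coords(self, coords: np.ndarray, **meta) -> "Configuration":
        return replace(self, coords=np.asarray(coords, dtype=float), **meta)


@dataclass
class ConfigurationSet:
    """A collection of configurations sharing one landmark scheme.

    ``(individual, side, replicate)`` triples must be unique.
    """

    scheme: LandmarkScheme
    configs: list[Configuration] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, int]] = set()
        for c in self.configs:
            if c.coords.shape != (self.scheme.n_points, self.scheme.dims):
                raise ValueError(
                    f"configuration {c.key} has shape {c.coords.shape}, scheme "
                    f"expects ({self.scheme.n_points}, {self.scheme.dims})"
                )
            if c.key in seen:
                raise ValueError(f"duplicate configuration key {c.key}")
            seen.add(c.key)

    def __len__(self) -> int:
        return len(self.configs)

    def __iter__(self):
        return iter(self.configs)

    def coords_array(self) -> np.ndarray:
        """Stack coordinates into an ``n_configs x n_points x dims`` array."""
        return np.stack([c.coords for c in self.configs])

    def individuals(self) -> list[str]:
        out: list[str] = []
        for c in self.configs:
            if c.individual not in out:
                out.append(c.individual)
        return out

    def subset(self, predicate) -> "ConfigurationSet":
        return ConfigurationSet(self.scheme, [c for c in self.configs if predicate(c)])

    def meta_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "individual": [c.individual for c in self.configs],
                "biotype": [c.biotype for c in self.configs],
                "lineage": [c.lineage for c in self.configs],
                "site": [c.site for c in self.configs],
                "dental_formula": [c.formula for c in self.configs],
                "session": [c.replicate for c in self.configs],
                "side": [c.side for c in self.configs],
            }
        )


@dataclass
class AlignedSet:
    """Procrustes-superimposed configurations.

    Attributes
    ----------
    source
        The configuration set that was aligned (in the same order as
        ``proc_coords`` rows).
    proc_coords
        ``n_configs x n_points x dims`` superimposed coordinates.
    centroid_sizes
        Original centroid size of each configuration.
    consensus
        Mean configuration (centroid at the origin; unit centroid size
        when scaling was applied).
    tangent
        ``n_configs x (n_points*dims)`` shape variables after projection
        to the tangent space at the consensus; ``None`` until projected.
    scaled
        Whether unit-centroid-size scaling was applied.
    """

    source: ConfigurationSet
    proc_coords: np.ndarray
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    tangent: np.ndarray | None = None
    scaled: bool = True

    def __post_init__(self) -> None:
        n = len(self.source)
        if self.proc_coords.shape[0] != n or self.centroid_sizes.shape[0] != n:
            raise ValueError("aligned arrays must match the number of configurations")
        if self.tangent is not None and self.tangent.shape[0] != n:
            raise ValueError("tangent row count must equal configuration count")

    @property
    def scheme(self) -> LandmarkScheme:
        return self.source.scheme

    def __len__(self) -> int:
        return len(self.source)
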