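"""Landmark scheme registry.

A :class:`LandmarkScheme` is the single source of truth for the semantics of
the points in one camera view of the carapace: how many points there are,
which of them are sliding semilandmarks and what their tangent chords are,
and -- for the two views with object symmetry (dorsal, posterior) -- which
points sit on the midline and how bilateral points pair up left/right.
Downstream modules take point semantics from the scheme, never from
positional assumptions.

Schemes are shipped in ``schemes.yaml`` next to this module, using the
1-based numbering of the published landmark definitions; indices are 0-based
everywhere in code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

VIEWS = ("dorsal", "lateral", "posterior")


@dataclass(frozen=True)
class LandmarkScheme:
    """Point semantics for one carapace view.

    All index collections are 0-based. ``pair_map`` maps each bilateral
    point to its mirror partner (an involution with no fixed points);
    ``sliding_neighbors`` maps each semilandmark to the two point indices
    whose chord defines its sliding tangent.
    """

    view: str
    n_points: int
    semilandmark_indices: frozenset[int]
    symmetric: bool
    midline_indices: frozenset[int]
    pair_map: Mapping[int, int]
    sliding_neighbors: Mapping[int, tuple[int, int]]
    repeatable_pc_count: int
    chains: tuple[tuple[int, ...], ...] = field(default=())

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n = self.n_points
        if n < 3:
            raise ValueError(f"{self.view}: scheme needs at least 3 points")
        all_idx = set(range(n))
        if not self.semilandmark_indices <= all_idx:
            raise ValueError(f"{self.view}: semilandmark index out of range")
        if self.symmetric:
            if not self.midline_indices:
                raise ValueError(f"{self.view}: symmetric view needs midline points")
            paired = set(self.pair_map)
            if paired & self.midline_indices:
                raise ValueError(f"{self.view}: midline and paired sets overlap")
            for i, j in self.pair_map.items():
                if i == j:
                    raise ValueError(f"{self.view}: pair map has fixed point {i}")
                if self.pair_map.get(j) != i:
                    raise ValueError(f"{self.view}: pair map is not an involution")
            if paired | self.midline_indices != all_idx:
                raise ValueError(f"{self.view}: pairs + midline must cover all points")
        for s in self.semilandmark_indices:
            a, b = self.sliding_neighbors[s]
            if a == b or s in (a, b):
                raise ValueError(f"{self.view}: bad sliding neighbors for {s}")

    @property
    def landmark_indices(self) -> frozenset[int]:
        return frozenset(range(self.n_points)) - self.semilandmark_indices

    def mirror_permutation(self) -> np.ndarray:
        """Index permutation that relabels left points as right and vice versa."""
        if not self.symmetric:
            raise ValueError(f"{self.view}: view has no object symmetry")
        perm = np.arange(self.n_points)
        for i, j in self.pair_map.items():
            perm[i] = j
        return perm

    def half_indices(self) -> np.ndarray:
        """Midline points plus one side's points, in scheme order.

        The retained side is the one whose indices are the smaller member of
        each bilateral pair.
        """
        if not self.symmetric:
            raise ValueError(f"{self.view}: view has no object symmetry")
        keep = set(self.midline_indices)
        keep.update(i for i, j in self.pair_map.items() if i < j)
        return np.array(sorted(keep), dtype=int)

    def half_scheme(self) -> "LandmarkScheme":
        """Scheme describing the half-configuration after symmetry reduction."""
        half = self.half_indices()
        remap = {old: new for new, old in enumerate(half)}
        kept = set(half.tolist())
        semis = frozenset(remap[s] for s in self.semilandmark_indices if s in kept)
        neighbors = {}
        for s in self.semilandmark_indices:
            if s not in kept:
                continue
            a, b = self.sliding_neighbors[s]
            if a in kept and b in kept:
                neighbors[remap[s]] = (remap[a], remap[b])
            else:  # chord endpoint lost to the other side: degrade to landmark
                semis = semis - {remap[s]}
        return LandmarkScheme(
            view=f"{self.view}_half",
            n_points=len(half),
            semilandmark_indices=semis,
            symmetric=False,
            midline_indices=frozenset(),
            pair_map={},
            sliding_neighbors=neighbors,
            repeatable_pc_count=self.repeatable_pc_count,
        )


def _scheme_from_dict(view: str, d: dict) -> LandmarkScheme:
    chains = tuple(tuple(i - 1 for i in chain) for chain in d.get("chains", []))
    semis: set[int] = set()
    neighbors: dict[int, tuple[int, int]] = {}
    for chain in chains:
        for k in range(1, len(chain) - 1):
            semis.add(chain[k])
            neighbors[chain[k]] = (chain[k - 1], chain[k + 1])
    pair_map: dict[int, int] = {}
    for i, j in d.get("pairs", []):
        pair_map[i - 1] = j - 1
        pair_map[j - 1] = i - 1
    return LandmarkScheme(
        view=view,
        n_points=int(d["n_points"]),
        semilandmark_indices=frozenset(semis),
        symmetric=bool(d["symmetric"]),
        midline_indices=frozenset(i - 1 for i in d.get("midline", [])),
        pair_map=pair_map,
        sliding_neighbors=neighbors,
        repeatable_pc_count=int(d["repeatable_pc_count"]),
        chains=chains,
    )


def load_registry(path: str | None = None) -> dict[str, LandmarkScheme]:
    """Load the scheme registry from ``path`` or the packaged ``schemes.yaml``."""
    if path is None:
        text = resources.files(__package__).joinpath("schemes.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {view: _scheme_from_dict(view, d) for view, d in raw["views"].items()}


_REGISTRY: dict[str, LandmarkScheme] | None = None


def get_scheme(view: str) -> LandmarkScheme:
    """Return the registered scheme for a view (``dorsal``/``lateral``/``posterior``)."""
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = load_registry()
    try:
        return _REGISTRY[view]
    except KeyError:
        raise KeyError(f"unknown view {view!r}; known: {sorted(_REGISTRY)}") from None
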