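"""Landmark-scheme description for bilaterally symmetric 2-D configurations.

A :class:`LandmarkScheme` declares, for a template of ``n_landmarks`` points,
which landmarks form bilateral (left/right) pairs, which lie on the midline,
and which are semilandmarks that may slide along a curve during
superimposition.  Indices are 1-based, matching the usual numbering of
digitizing software; 0-based views are provided for array work.

The built-in :func:`viper_head_scheme` encodes the 40-landmark dorsal
head-shape template for *Vipera ursinii*: 18 bilateral pairs, 4 midline
landmarks (1, 34, 35, 40) and 12 sliding semilandmarks (18-29) on the
supraocular and posterior head outlines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = ["LandmarkScheme", "viper_head_scheme"]


@dataclass(frozen=True)
class LandmarkScheme:
    """Declarative description of a bilaterally structured landmark template.

    Parameters
    ----------
    n_landmarks : int
        Total number of landmarks per configuration.
    pairs : sequence of (int, int)
        1-based (right, left) index pairs of bilaterally homologous landmarks.
    midline : sequence of int
        1-based indices of landmarks on the midline (sagittal axis).
    semilandmarks : sequence of (int, int, int)
        1-based triples ``(index, neighbor_before, neighbor_after)`` naming a
        sliding semilandmark and the two curve neighbors that define its
        sliding chord.
    """

    n_landmarks: int
    pairs: tuple[tuple[int, int], ...]
    midline: tuple[int, ...]
    semilandmarks: tuple[tuple[int, int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(tuple(p) for p in self.pairs))
        object.__setattr__(self, "midline", tuple(self.midline))
        object.__setattr__(
            self, "semilandmarks", tuple(tuple(s) for s in self.semilandmarks)
        )
        seen: set[int] = set()
        for left, right in self.pairs:
            for idx in (left, right):
                self._check_index(idx)
                if idx in seen:
                    raise ValueError(f"landmark {idx} appears in more than one role")
                seen.add(idx)
        for idx in self.midline:
            self._check_index(idx)
            if idx in seen:
                raise ValueError(f"landmark {idx} appears in more than one role")
            seen.add(idx)
        if 2 * len(self.pairs) + len(self.midline) != self.n_landmarks:
            raise ValueError(
                "pairs and midline must partition the landmarks: "
                f"2*{len(self.pairs)} + {len(self.midline)} != {self.n_landmarks}"
            )
        for idx, before, after in self.semilandmarks:
            for j in (idx, before, after):
                self._check_index(j)
            if len({idx, before, after}) != 3:
                raise ValueError(
                    f"semilandmark {idx}: neighbors must be distinct from it and "
                    "from each other"
                )

    def _check_index(self, idx: int) -> None:
        if not 1 <= idx <= self.n_landmarks:
            raise ValueError(
                f"landmark index {idx} outside 1..{self.n_landmarks}"
            )

    # ---- 0-based convenience views -------------------------------------
    @property
    def pairs0(self) -> np.ndarray:
        """Pairs as a (n_pairs, 2) int array of 0-based indices."""
        return np.asarray(self.pairs, dtype=int) - 1

    @property
    def midline0(self) -> np.ndarray:
        """Midline indices, 0-based."""
        return np.asarray(self.midline, dtype=int) - 1

    @property
    def semilandmarks0(self) -> np.ndarray:
        """Semilandmark (index, before, after) triples, 0-based."""
        if not self.semilandmarks:
            return np.zeros((0, 3), dtype=int)
        return np.asarray(self.semilandmarks, dtype=int) - 1

    @property
    def symmetric_dimension(self) -> int:
        """Dimension of the symmetric shape (tangent) space.

        One degree of freedom per paired-landmark coordinate on one side plus
        one per midline landmark (position along the axis), minus axial
        translation and scale: ``2*n_pairs + n_midline - 2``.
        """
        return 2 * len(self.pairs) + len(self.midline) - 2

    def reflection_permutation(self) -> np.ndarray:
        """0-based permutation mapping each landmark to its mirror partner."""
        perm = np.arange(self.n_landmarks)
        for left, right in self.pairs0:
            perm[left], perm[right] = right, left
        return perm

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_landmarks": self.n_landmarks,
            "pairs": [list(p) for p in self.pairs],
            "midline": list(self.midline),
            "semilandmarks": [list(s) for s in self.semilandmarks],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkScheme":
        return cls(
            n_landmarks=int(d["n_landmarks"]),
            pairs=tuple(tuple(p) for p in d["pairs"]),
            midline=tuple(d["midline"]),
            semilandmarks=tuple(tuple(s) for s in d.get("semilandmarks", ())),
        )

    @classmethod
    def from_yaml(cls, path) -> "LandmarkScheme":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def viper_head_scheme() -> LandmarkScheme:
    """The 40-landmark dorsal viper-head template.

    18 bilateral pairs (even = right, odd = left for the fixed landmarks),
    4 midline landmarks (1 apical tip, 34 posterior frontal, 35 anterior
    parietal contact, 40 posterior parietal tip) and 12 sliding
    semilandmarks: 18-21 on the supraocular outline (between landmarks 8-10
    and 9-11) and 22-29 on the posterior head border (between 10-16 and
    11-17).
    """
    pairs = (
        (2, 3), (4, 5), (6, 7), (8, 9), (10, 11), (12, 13), (14, 15),
        (16, 17),
        (18, 19), (20, 21),            # supraocular outline semilandmarks
        (22, 23), (24, 25), (26, 27), (28, 29),  # posterior border semis
        (30, 31), (32, 33), (36, 37), (38, 39),
    )
    midline = (1, 34, 35, 40)
    semilandmarks = (
        # supraocular outline: 8 - 18 - 20 - 10 (right), 9 - 19 - 21 - 11 (left)
        (18, 8, 20), (20, 18, 10),
        (19, 9, 21), (21, 19, 11),
        # posterior head border: 10 - 22 - 24 - 26 - 28 - 16 (right side)
        (22, 10, 24), (24, 22, 26), (26, 24, 28), (28, 26, 16),
        # 11 - 23 - 25 - 27 - 29 - 17 (left side)
        (23, 11, 25), (25, 23, 27), (27, 25, 29), (29, 27, 17),
    )
    return LandmarkScheme(
        n_landmarks=40, pairs=pairs, midline=midline, semilandmarks=semilandmarks
    )
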