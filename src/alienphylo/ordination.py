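"""Principal Coordinates Analysis of between-assemblage distance matrices.

Classical scaling: Gower double-centering of −½ d², symmetric
eigendecomposition, coordinates = eigenvectors × √eigenvalue for the
positive eigenvalues.  Nearest-taxon distances between nested assemblages
are generally non-Euclidean, so negative eigenvalues can appear; they are
dropped from the coordinates, excluded from the variance denominator, and
their total magnitude is reported (no Cailliez/Lingoes correction is
applied — the default behaviour of standard classical-scaling routines).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import OrdinationError

__all__ = ["AssemblageDistanceMatrix", "PCoAResult", "pcoa"]

_EIG_TOL = 1e-10  # relative cutoff separating positive / zero eigenvalues


@dataclass(frozen=True)
class AssemblageDistanceMatrix:
    """Symmetric non-negative distances among named assemblages."""

    names: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self):
        n = len(self.names)
        d = np.asarray(self.d, dtype=np.float64)
        if d.shape != (n, n):
            raise OrdinationError("matrix shape does not match names")
        if not np.allclose(d, d.T, atol=1e-12):
            raise OrdinationError("distance matrix must be symmetric")
        if (d < 0).any():
            raise OrdinationError("distance matrix must be non-negative")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise OrdinationError("distance matrix must have a zero diagonal")
        object.__setattr__(self, "d", d)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.names), columns=list(self.names))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="")

    @classmethod
    def from_csv(cls, path: str | Path) -> "AssemblageDistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(names=tuple(str(c) for c in df.columns), d=df.to_numpy(dtype=np.float64))


@dataclass(frozen=True)
class PCoAResult:
    """Eigenvalues, point coordinates and per-axis variance fractions.

    Coordinates cover positive eigenvalues only; ``variance_explained`` is
    each positive eigenvalue over the sum of positive eigenvalues, so it sums
    to 1 over the retained axes; ``negative_eigenvalue_mass`` is the summed
    magnitude of any negative eigenvalues (0 for Euclidean input).
    """

    names: tuple[str, ...]
    eigenvalues: np.ndarray  # all eigenvalues, sorted descending
    coordinates: np.ndarray  # (n_points, n_positive_axes)
    variance_explained: np.ndarray
    negative_eigenvalue_mass: float

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def coordinates_frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.n_axes)]
        df = pd.DataFrame(self.coordinates, columns=cols)
        df.insert(0, "assemblage", list(self.names))
        return df

    def save(self, coords_csv: str | Path, eigen_json: str | Path) -> None:
        self.coordinates_frame().to_csv(coords_csv, index=False)
        payload = {
            "eigenvalues": [float(v) for v in self.eigenvalues],
            "variance_explained": [float(v) for v in self.variance_explained],
            "negative_eigenvalue_mass": float(self.negative_eigenvalue_mass),
        }
        Path(eigen_json).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def pcoa(adm: AssemblageDistanceMatrix) -> PCoAResult:
    """Classical scaling of an assemblage distance matrix.

    For a Euclidean input the pairwise distances among the full-dimensional
    coordinates reproduce the matrix (to ~1e-8).  Axis signs are fixed by
    making each axis's largest-magnitude coordinate positive, so the output
    is fully deterministic.
    """
    d = adm.d
    n = d.shape[0]
    if n < 2:
        raise OrdinationError("pcoa needs at least 2 points")
    a = -0.5 * d**2
    centerer = np.eye(n) - np.full((n, n), 1.0 / n)
    b = centerer @ a @ centerer
    b = (b + b.T) / 2.0
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    scale = max(abs(eigval[0]), abs(eigval[-1]), 1.0)
    positive = eigval > _EIG_TOL * scale
    coords = eigvec[:, positive] * np.sqrt(eigval[positive])
    # sign convention: largest-|coordinate| entry of each axis is positive
    for j in range(coords.shape[1]):
        k = np.argmax(np.abs(coords[:, j]))
        if coords[k, j] < 0:
            coords[:, j] = -coords[:, j]
    pos_sum = eigval[positive].sum()
    variance = eigval[positive] / pos_sum if pos_sum > 0 else np.zeros(0)
    negative_mass = float(-eigval[eigval < -_EIG_TOL * scale].sum())
    return PCoAResult(
        names=adm.names,
        eigenvalues=eigval,
        coordinates=coords,
        variance_explained=variance,
        negative_eigenvalue_mass=negative_mass,
    )


def pairwise_comdistnt_matrix(
    dm,
    assemblages,
    names: Sequence[str] | None = None,
    *,
    exclude_conspecifics: bool = False,
) -> AssemblageDistanceMatrix:
    """Between-assemblage nearest-taxon distance matrix (zero diagonal).

    ``assemblages`` maps a name to a species set, or is an
    :class:`~alienphylo.checklist.AssemblageSet` when ``names`` is omitted.
    """
    from .checklist import AssemblageSet
    from .phylo import comdistnt

    if isinstance(assemblages, AssemblageSet):
        mapping = {name: assemblages[name] for name in AssemblageSet.NAMES}
    else:
        mapping = dict(assemblages)
    keys = tuple(names) if names is not None else tuple(mapping)
    n = len(keys)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = comdistnt(
                dm,
                mapping[keys[i]],
                mapping[keys[j]],
                exclude_conspecifics=exclude_conspecifics,
            )
    return AssemblageDistanceMatrix(names=keys, d=d)
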