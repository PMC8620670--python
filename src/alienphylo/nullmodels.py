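"""Nearest taxon index: standardized effect size of MNTD under a pool null.

The null model maintains species richness: every alien species goes into a
reference pool, and null assemblages are uniform draws (without replacement)
of the observed richness from that pool.  The index is

    NTI = −(MNTD_obs − mean(MNTD_null)) / sd(MNTD_null)

with the sample (n−1) standard deviation.  Positive NTI means the observed
assemblage is more closely related than random same-richness draws
(phylogenetic clustering); negative means overdispersion; zero means the
assemblage is indistinguishable from a random draw.

When the number of distinct same-richness subsets is small the null is
enumerated exhaustively instead of sampled; when the assemblage *is* the
pool, richness-preserving draws reproduce the pool exactly, the null has zero
spread and NTI is degenerately undefined — this is flagged, and a
bootstrap-with-replacement null is available as an alternative resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal

import numpy as np

from .checklist import AssemblageSet
from .errors import AssemblageError, NullModelError
from .phylo import PatristicMatrix, mntd, mntd_of_index_sets

__all__ = ["NTIResult", "sample_null_assemblage", "nti", "nti_all"]

#: Exhaustive enumeration replaces Monte Carlo when C(|pool|, k) is at most this.
EXHAUSTIVE_LIMIT = 10_000


@dataclass(frozen=True)
class NTIResult:
    """Observed MNTD, its null distribution summary, and the index."""

    assemblage_name: str
    richness: int
    mntd_observed: float
    null_mean: float
    null_sd: float
    nti: float  # NaN when undefined
    n_draws: int
    mode: Literal["monte_carlo", "exhaustive", "bootstrap"]
    seed: int | None
    undefined: bool = False
    diagnostic: str | None = None

    def to_dict(self) -> dict:
        d = {
            "assemblage_name": self.assemblage_name,
            "richness": self.richness,
            "mntd_observed": self.mntd_observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "nti": None if math.isnan(self.nti) else self.nti,
            "n_draws": self.n_draws,
            "mode": self.mode,
            "seed": self.seed,
            "undefined": self.undefined,
            "diagnostic": self.diagnostic,
        }
        return d


def sample_null_assemblage(
    pool: Iterable[str], richness: int, rng: np.random.Generator
) -> frozenset[str]:
    """Uniform draw of ``richness`` species from the pool, without replacement.

    The pool is sorted internally so the draw depends only on the seed, not on
    set iteration order.
    """
    pool_list = sorted(set(pool))
    if richness > len(pool_list):
        raise NullModelError(f"richness {richness} exceeds pool size {len(pool_list)}")
    if richness < 2:
        raise NullModelError("null assemblages need richness >= 2")
    picks = rng.choice(len(pool_list), size=richness, replace=False)
    return frozenset(pool_list[i] for i in picks)


def _null_index_sets(
    n_pool: int,
    richness: int,
    n_draws: int,
    rng: np.random.Generator,
    mode: str,
) -> tuple[np.ndarray, str]:
    """Tip-index sets of the null assemblages and the mode actually used."""
    if mode == "auto":
        mode = "exhaustive" if math.comb(n_pool, richness) <= EXHAUSTIVE_LIMIT else "monte_carlo"
    if mode == "exhaustive":
        sets = np.array(list(combinations(range(n_pool), richness)), dtype=np.intp)
    elif mode == "monte_carlo":
        # random permutations truncated to k: uniform k-subsets
        sets = np.argsort(rng.random((n_draws, n_pool)), axis=1)[:, :richness]
    elif mode == "bootstrap":
        sets = rng.integers(0, n_pool, size=(n_draws, richness))
    else:
        raise NullModelError(f"unknown null mode {mode!r}")
    return sets, mode


def nti(
    dm: PatristicMatrix,
    assemblage: Iterable[str],
    pool: Iterable[str],
    *,
    n_draws: int = 1000,
    seed: int | None = None,
    mode: Literal["auto", "monte_carlo", "exhaustive", "bootstrap"] = "auto",
    assemblage_name: str = "assemblage",
) -> NTIResult:
    """Nearest taxon index of one assemblage against a reference pool.

    ``mode="auto"`` enumerates all same-richness subsets when there are at
    most ``EXHAUSTIVE_LIMIT`` of them, otherwise draws ``n_draws`` Monte-Carlo
    assemblages.  ``mode="bootstrap"`` samples pool members with replacement
    (the alternative for a degenerate assemblage-equals-pool null).  A null
    with zero spread yields an undefined (NaN) index with a diagnostic, never
    ±inf or 0.
    """
    assemblage = sorted(set(assemblage))
    pool_list = sorted(set(pool))
    if not set(assemblage) <= set(pool_list):
        raise NullModelError(
            f"assemblage not contained in pool: {sorted(set(assemblage) - set(pool_list))[:5]}"
        )
    if len(assemblage) < 2:
        raise AssemblageError(f"nti needs at least 2 taxa, got {len(assemblage)}")
    if n_draws < 1:
        raise NullModelError("n_draws must be >= 1")
    richness = len(assemblage)
    observed = mntd(dm, assemblage)
    pool_idx = dm.indices(pool_list, what="pool")
    rng = np.random.default_rng(seed)
    sets, used_mode = _null_index_sets(len(pool_list), richness, n_draws, rng, mode)
    null_values = mntd_of_index_sets(dm, pool_idx[sets])
    null_mean = float(null_values.mean())
    null_sd = float(null_values.std(ddof=1)) if len(null_values) > 1 else 0.0

    undefined = not (null_sd > 0)
    if undefined:
        value = float("nan")
        diagnostic = (
            "null distribution has zero spread (every same-richness draw has the "
            "same MNTD" + ("; assemblage equals pool" if richness == len(pool_list) else "")
            + "); NTI is undefined"
        )
    else:
        value = -(observed - null_mean) / null_sd
        diagnostic = None
    return NTIResult(
        assemblage_name=assemblage_name,
        richness=richness,
        mntd_observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        nti=value,
        n_draws=len(null_values),
        mode=used_mode,
        seed=seed,
        undefined=undefined,
        diagnostic=diagnostic,
    )


def nti_all(
    dm: PatristicMatrix,
    assemblages: AssemblageSet,
    *,
    n_draws: int = 1000,
    seed: int | None = None,
    pool: Iterable[str] | None = None,
    degenerate_pool_mode: Literal["flag", "bootstrap"] = "flag",
) -> list[NTIResult]:
    """NTI of all five invasion-stage assemblages against the alien pool.

    Every assemblage is standardized against the SAME reference pool (by
    default the alien set itself).  Each assemblage gets an independent
    sub-seed (master seed + stable assemblage index) so adding or removing an
    assemblage does not shift the others' draws.  For an assemblage identical
    to the pool the richness-preserving null is degenerate; the default flags
    it undefined, ``degenerate_pool_mode="bootstrap"`` switches that
    assemblage to a with-replacement null instead.
    """
    pool_set = frozenset(assemblages.alien if pool is None else pool)
    results = []
    for index, name in enumerate(AssemblageSet.NAMES):
        members = assemblages[name]
        sub_seed = None if seed is None else seed + index
        mode: str = "auto"
        if members == pool_set and degenerate_pool_mode == "bootstrap":
            mode = "bootstrap"
        results.append(
            nti(
                dm,
                members,
                pool_set,
                n_draws=n_draws,
                seed=sub_seed,
                mode=mode,  # type: ignore[arg-type]
                assemblage_name=name,
            )
        )
    return results
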