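"""Alpha and beta phylogenetic metrics with permutation-null effect sizes.

Within-community structure is summarized by the mean pairwise distance (MPD)
and the mean nearest taxon distance (MNTD); turnover between communities by
the Jaccard similarity and by betaMPD / betaMNTD, the between-community
analogues of MPD and MNTD (the comdist/comdistnt convention: shared taxa
contribute zero distances to betaMPD, and a taxon shared by both communities
has a nearest cross-community distance of zero).

betaNRI and betaNTI are the *negative* standardized effect sizes of betaMPD
and betaMNTD against a permutation null: positive values mean lower turnover
than chance.  The default null ("pool") shuffles taxon identities across the
whole species pool, preserving community sizes and shared-taxon structure
(the unconstrained null model); an "independent" variant redraws each
community independently from the pool, which breaks the shared structure —
both are provided because literature wording on the null is ambiguous.

All metrics are presence-absence by default; abundances carried by the
community matrix are not used unless explicitly requested upstream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .trees import CopheneticMatrix

__all__ = [
    "MetricError",
    "SESResult",
    "mpd",
    "mntd",
    "jaccard",
    "beta_mpd",
    "beta_mntd",
    "null_ses",
    "all_pair_metrics",
    "DEFAULT_SES_THRESHOLD",
]

DEFAULT_SES_THRESHOLD = 1.96


class MetricError(ValueError):
    pass


def _indices(taxa: Sequence[str], D: CopheneticMatrix, minimum: int = 1) -> np.ndarray:
    if len(set(taxa)) != len(taxa):
        raise MetricError("duplicate taxa in community")
    if len(taxa) < minimum:
        raise MetricError(f"need at least {minimum} taxa, got {len(taxa)}")
    return D.index(taxa)


def mpd(taxa: Sequence[str], D: CopheneticMatrix) -> float:
    """Mean pairwise distance over all unordered pairs of distinct taxa."""
    idx = _indices(taxa, D, minimum=2)
    sub = D.values[np.ix_(idx, idx)]
    m = len(idx)
    return float(sub[np.triu_indices(m, k=1)].mean())


def mntd(taxa: Sequence[str], D: CopheneticMatrix) -> float:
    """Mean distance from each taxon to its nearest co-occurring taxon."""
    idx = _indices(taxa, D, minimum=2)
    sub = D.values[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def jaccard(a: Sequence[str], b: Sequence[str]) -> float:
    """|a n b| / |a u b| on presence-absence taxon sets."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise MetricError("Jaccard similarity of an empty community")
    return len(sa & sb) / len(sa | sb)


def beta_mpd(a: Sequence[str], b: Sequence[str], D: CopheneticMatrix) -> float:
    """Mean cophenetic distance over all cross-community taxon pairs.

    Shared taxa contribute D(i,i) = 0 pairs (comdist convention), so the
    value drops for overlapping communities.
    """
    ia, ib = _indices(a, D), _indices(b, D)
    return float(D.values[np.ix_(ia, ib)].mean())


def beta_mntd(a: Sequence[str], b: Sequence[str], D: CopheneticMatrix) -> float:
    """Mean distance of every taxon to its nearest taxon in the other community.

    Averaged over both directions; a shared taxon has distance zero.
    """
    ia, ib = _indices(a, D), _indices(b, D)
    cross = D.values[np.ix_(ia, ib)]
    return float(np.concatenate([cross.min(axis=1), cross.min(axis=0)]).mean())


# -- vectorized batch versions used by the permutation null -----------------

try:  # numba keeps the O(n_rand * na * nb) null loops cache-local
    import numba

    @numba.njit(cache=True, fastmath=True)
    def _beta_mpd_batch_nb(A, B, V):  # pragma: no cover - compiled
        r, na = A.shape
        nb = B.shape[1]
        out = np.empty(r)
        for k in range(r):
            s = 0.0
            for i in range(na):
                ai = A[k, i]
                for j in range(nb):
                    s += V[ai, B[k, j]]
            out[k] = s / (na * nb)
        return out

    @numba.njit(cache=True, fastmath=True)
    def _beta_mntd_batch_nb(A, B, V):  # pragma: no cover - compiled
        r, na = A.shape
        nb = B.shape[1]
        out = np.empty(r)
        for k in range(r):
            s = 0.0
            for i in range(na):
                ai = A[k, i]
                m = np.inf
                for j in range(nb):
                    d = V[ai, B[k, j]]
                    if d < m:
                        m = d
                s += m
            for j in range(nb):
                bj = B[k, j]
                m = np.inf
                for i in range(na):
                    d = V[A[k, i], bj]
                    if d < m:
                        m = d
                s += m
            out[k] = s / (na + nb)
        return out

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _beta_mpd_batch(A: np.ndarray, B: np.ndarray, V: np.ndarray) -> np.ndarray:
    # A: (r, na) and B: (r, nb) integer index arrays into V
    if _HAVE_NUMBA:
        return _beta_mpd_batch_nb(A, B, V)
    return V[A[:, :, None], B[:, None, :]].mean(axis=(1, 2))


def _beta_mntd_batch(A: np.ndarray, B: np.ndarray, V: np.ndarray) -> np.ndarray:
    if _HAVE_NUMBA:
        return _beta_mntd_batch_nb(A, B, V)
    cross = V[A[:, :, None], B[:, None, :]]
    return (cross.min(axis=2).sum(axis=1) + cross.min(axis=1).sum(axis=1)) / (
        A.shape[1] + B.shape[1]
    )


_BATCH = {"beta_mpd": _beta_mpd_batch, "beta_mntd": _beta_mntd_batch}
_PLAIN = {"beta_mpd": beta_mpd, "beta_mntd": beta_mntd}


@dataclass
class SESResult:
    """Observed metric against its permutation null.

    ``ses`` is (observed - null mean) / null sd; ``negated_ses`` is the
    betaNRI (for betaMPD) or betaNTI (for betaMNTD), where positive values
    indicate lower turnover than expected by chance.  ``significant`` is set
    iff |negated_ses| exceeds ``threshold`` and the null is not degenerate.
    """

    observed: float
    null_mean: float
    null_sd: float
    n_rand: int
    metric: str
    threshold: float = DEFAULT_SES_THRESHOLD
    degenerate: bool = False

    @property
    def ses(self) -> float:
        if self.degenerate:
            return float("nan")
        return (self.observed - self.null_mean) / self.null_sd

    @property
    def negated_ses(self) -> float:
        return -self.ses

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and abs(self.negated_ses) > self.threshold

    @property
    def low_turnover(self) -> bool:
        return self.significant and self.negated_ses > 0


def _null_samples(
    rng: np.random.Generator,
    ia: np.ndarray,
    ib: np.ndarray,
    pool_idx: np.ndarray,
    n_rand: int,
    null_model: str,
) -> tuple[np.ndarray, np.ndarray]:
    m = len(pool_idx)
    pos = {p: k for k, p in enumerate(pool_idx)}
    if null_model == "pool":
        # one bijection of pool labels per randomization: sizes and
        # shared-taxon structure of (a, b) are preserved
        union = np.array(sorted(set(ia) | set(ib)), dtype=int)
        upos = {p: k for k, p in enumerate(union)}
        s = len(union)
        draw = np.argsort(rng.random((n_rand, m)), axis=1)[:, :s]
        targets = pool_idx[draw]  # (n_rand, s) random injections union->pool
        A = targets[:, [upos[p] for p in ia]]
        B = targets[:, [upos[p] for p in ib]]
        return A, B
    if null_model == "independent":
        na, nb = len(ia), len(ib)
        A = pool_idx[np.argsort(rng.random((n_rand, m)), axis=1)[:, :na]]
        B = pool_idx[np.argsort(rng.random((n_rand, m)), axis=1)[:, :nb]]
        return A, B
    raise MetricError(f"unknown null model {null_model!r}")


def null_ses(
    a: Sequence[str],
    b: Sequence[str],
    D: CopheneticMatrix,
    metric: str,
    pool: Sequence[str],
    n_rand: int = 999,
    seed: int | np.random.SeedSequence = 0,
    null_model: str = "pool",
    threshold: float = DEFAULT_SES_THRESHOLD,
) -> SESResult:
    """Standardized effect size of betaMPD/betaMNTD under a permutation null.

    Requires ``a u b`` to be a subset of ``pool`` and ``n_rand >= 100``.  A
    zero null standard deviation (e.g. a star phylogeny) sets the
    ``degenerate`` flag: the SES is undefined and no significance call is
    made.  Deterministic under a fixed seed.
    """
    if metric not in _BATCH:
        raise MetricError(f"metric must be one of {sorted(_BATCH)}")
    if n_rand < 100:
        raise MetricError("n_rand must be >= 100")
    pool_idx = _indices(pool, D, minimum=2)
    ia, ib = _indices(a, D), _indices(b, D)
    if not (set(ia) | set(ib)) <= set(pool_idx):
        raise MetricError("a u b must be contained in the pool")
    observed = _PLAIN[metric](a, b, D)
    rng = np.random.default_rng(seed)
    A, B = _null_samples(rng, ia, ib, pool_idx, n_rand, null_model)
    nulls = _BATCH[metric](A, B, D.values)
    null_mean = float(nulls.mean())
    null_sd = float(nulls.std(ddof=1))
    degenerate = not np.isfinite(null_sd) or null_sd <= 1e-12
    return SESResult(
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        n_rand=n_rand,
        metric=metric,
        threshold=threshold,
        degenerate=degenerate,
    )


def _pair_seed(seed: int, id_a: str, id_b: str) -> np.random.SeedSequence:
    # derived from the community ids so results do not depend on input order
    ha = zlib.crc32(id_a.encode())
    hb = zlib.crc32(id_b.encode())
    lo, hi = sorted((ha, hb))
    return np.random.SeedSequence([int(seed), lo, hi])


def all_pair_metrics(
    cm,
    D: CopheneticMatrix,
    n_rand: int = 999,
    seed: int = 0,
    null_model: str = "pool",
    threshold: float = DEFAULT_SES_THRESHOLD,
    pool: Optional[Sequence[str]] = None,
    progress: Optional[Callable[[int, int], None]] = None,
    compute_ses: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute all community and community-pair metrics in one pass.

    Returns ``(pairs, communities)``: one row per unordered community pair
    (Jaccard, betaMPD, betaMNTD, betaNRI, betaNTI, degeneracy flags) and one
    row per community (richness, MPD, MNTD, and their common logarithms;
    NaN for single-taxon communities).  Each pair draws its own random
    stream keyed on the pair's community ids, so the table is invariant to
    community input order and resumable chunk by chunk.  ``compute_ses=False``
    skips the permutation nulls (no betaNRI/betaNTI columns) when only the
    raw metrics are needed.
    """
    ids = cm.ids
    taxa_by_comm = {c: cm.taxa_of(c) for c in ids}
    pool = list(pool) if pool is not None else list(cm.taxa)

    comm_rows = []
    for c in ids:
        taxa = taxa_by_comm[c]
        if len(taxa) >= 2:
            c_mpd, c_mntd = mpd(taxa, D), mntd(taxa, D)
        else:
            c_mpd = c_mntd = float("nan")
        comm_rows.append(
            {
                "community": c,
                "n_taxa": len(taxa),
                "mpd": c_mpd,
                "mntd": c_mntd,
                "log10_mpd": np.log10(c_mpd) if c_mpd and c_mpd > 0 else float("nan"),
                "log10_mntd": np.log10(c_mntd) if c_mntd and c_mntd > 0 else float("nan"),
            }
        )

    pair_rows = []
    pairs = [(ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))]
    for k, (ca, cb) in enumerate(pairs):
        a, b = taxa_by_comm[ca], taxa_by_comm[cb]
        row = {"comm_a": ca, "comm_b": cb, "jaccard": jaccard(a, b)}
        if compute_ses:
            children = _pair_seed(seed, ca, cb).spawn(2)
            for metric, stream, (nri_col, deg_col) in (
                ("beta_mpd", children[0], ("beta_nri", "beta_nri_degenerate")),
                ("beta_mntd", children[1], ("beta_nti", "beta_nti_degenerate")),
            ):
                res = null_ses(
                    a, b, D, metric, pool,
                    n_rand=n_rand, seed=stream,
                    null_model=null_model, threshold=threshold,
                )
                row[metric] = res.observed
                row[nri_col] = res.negated_ses
                row[deg_col] = res.degenerate
        else:
            row["beta_mpd"] = beta_mpd(a, b, D)
            row["beta_mntd"] = beta_mntd(a, b, D)
        pair_rows.append(row)
        if progress is not None:
            progress(k + 1, len(pairs))

    return pd.DataFrame(pair_rows), pd.DataFrame(comm_rows)
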