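"""Re-insertion null model and the positional bias test.

The question: are LCR centre positions distributed the way they would be
if each LCR had been dropped uniformly at random into its own protein?
The null is built empirically -- for every observed LCR of length ``w``
within a protein of length ``L``, the region is conceptually excised and
re-inserted ``n_reps`` times at a start drawn uniformly from the
admissible range ``{1, ..., L - w + 1}``.  Sequence content is irrelevant
to position, so re-insertion reduces to arithmetic on coordinates.  The
observed distribution of folded centre positions is then compared to the
pooled null with a two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

DEFAULT_N_REPS = 1000


def fold(x):
    """Map normalised positions onto the centre-to-extremity scale [0, 0.5]."""
    x = np.asarray(x, dtype=np.float64)
    return np.minimum(x, 1.0 - x)


def reinsertion_null(
    protein_length: int,
    lcr_length: int,
    n_reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Normalised centre positions of ``n_reps`` uniform re-insertions.

    Starts are drawn uniformly from ``{1, ..., L - w + 1}``; each centre is
    ``(2s + w - 1) / (2L)``.  Raises if the region is longer than the
    protein (no admissible position).
    """
    L, w = int(protein_length), int(lcr_length)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if w > L:
        raise ValueError(f"LCR length {w} exceeds protein length {L}")
    s = rng.integers(1, L - w + 2, size=int(n_reps))
    return (2 * s + w - 1) / (2.0 * L)


@dataclass
class NullPositionSample:
    """Per-LCR and pooled null centre positions (`per_lcr` is n_lcr x n_reps)."""

    per_lcr: np.ndarray
    n_reps: int
    seed: int | None = None

    @property
    def pooled(self) -> np.ndarray:
        return self.per_lcr.reshape(-1)


def build_position_null(
    lcr_shapes: Iterable[tuple[int, int]],
    n_reps: int = DEFAULT_N_REPS,
    *,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> NullPositionSample:
    """Pooled re-insertion null for a collection of (protein_length, lcr_length).

    Every LCR contributes exactly ``n_reps`` replicates, so pooling weights
    each LCR equally.  Deterministic given ``seed`` (or a supplied ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = [reinsertion_null(L, w, n_reps, rng) for L, w in lcr_shapes]
    if not rows:
        raise ValueError("no LCRs supplied to build a null from")
    return NullPositionSample(per_lcr=np.vstack(rows), n_reps=int(n_reps), seed=seed)


@dataclass
class PositionalTestResult:
    """Two-sample KS comparison of observed vs null centre positions."""

    D: float
    p: float
    n_obs: int
    n_null: int
    folded: bool


def positional_test(
    observed: Sequence[float],
    null: NullPositionSample | np.ndarray,
    *,
    folded: bool = True,
    min_obs: int = 3,
) -> PositionalTestResult:
    """Two-sample Kolmogorov-Smirnov test of observed positions vs the null.

    ``observed`` are normalised centre positions; both samples are folded
    onto [0, 0.5] before comparison unless ``folded=False`` (folding is
    idempotent, so already-folded inputs are safe).  The null is empirical
    and protein-length-dependent, hence a two-sample test against the
    pooled replicates rather than a one-sample test against a fitted CDF.
    """
    obs = np.asarray(observed, dtype=np.float64)
    pool = null.pooled if isinstance(null, NullPositionSample) else np.asarray(null, float)
    if obs.size < min_obs:
        raise ValueError(
            f"need at least {min_obs} observed positions for a meaningful "
            f"KS comparison, got {obs.size}"
        )
    if pool.size == 0:
        raise ValueError("null sample is empty")
    if folded:
        obs = fold(obs)
        pool = fold(pool)
    res = sps.ks_2samp(obs, pool, alternative="two-sided", method="asymp")
    return PositionalTestResult(
        D=float(res.statistic),
        p=float(res.pvalue),
        n_obs=int(obs.size),
        n_null=int(pool.size),
        folded=folded,
    )
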