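"""Permutation null model, phylogenetic-trace correction, Z-scores, B-cutoff.

Observed mutual information is compared against the distribution obtained
by randomly re-connecting TF-site pairs: one global sequence of
``n_shuffles`` permutations is drawn and every column pair is scored under
each of them.  The per-pair null mean and s.d. yield

    Z_ij = ( I_ij - E(I~_ij) ) / sigma(I~_ij)

after an affine trace correction that widens the null where shared
ancestry inflates MI across the board.  The number k* of significant pairs
is chosen by the Bernoulli cutoff: minimize over k the probability of
seeing >= k successes among M Bernoulli trials with success probability
equal to the Gaussian upper tail at the k-th largest Z.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import norm

from .alignments import GAP, PairedAlignmentSet, PairRecord
from .corrstats import (
    correlation_matrix,
    joint_count_tensor,
    mi_matrix_from_counts,
    onehot_encodings,
)
from .substitution import SubstitutionModel

logger = logging.getLogger(__name__)

LOG10_HALF = math.log10(0.5)


@dataclass
class NullModel:
    """Per-pair null mean/s.d. of shuffled MI plus the trace correction."""

    E: np.ndarray                  # raw null mean, (Ls, Lp)
    sd: np.ndarray                 # raw null s.d., (Ls, Lp)
    n_shuffles: int
    rng_seed: int
    trace_alpha: float = 1.0
    trace_beta: float = 0.0
    E_corrected: np.ndarray | None = None
    sd_corrected: np.ndarray | None = None

    @property
    def effective_E(self) -> np.ndarray:
        return self.E if self.E_corrected is None else self.E_corrected

    @property
    def effective_sd(self) -> np.ndarray:
        return self.sd if self.sd_corrected is None else self.sd_corrected


@dataclass
class CorrelationResult:
    """Z matrix, ranked pairs, B-cutoff curve and the selected pair set."""

    Z: np.ndarray                       # (Ls, Lp); NaN where not assessable
    assessable: np.ndarray              # bool mask
    ranked: list[tuple[int, int, float]]  # (j, i, Z) sorted by Z descending
    log10_B: np.ndarray                 # B-curve over k = 1..M (log10)
    k_star: int
    selected: list[tuple[int, int, float]]
    provenance: dict = field(default_factory=dict)

    @property
    def min_log10_p(self) -> float:
        """log10 of the B-cutoff global minimum (1.0 -> 0.0 if nothing selected)."""
        if self.log10_B.size == 0:
            return 0.0
        return float(self.log10_B.min())


# ---------------------------------------------------------------------------
# shuffling


def _split_weights(pset: PairedAlignmentSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-record (w(r), w(s)); falls back to (record weight, 1) when the
    per-sequence weight tables are absent."""
    if pset.tf_weights and pset.site_weights:
        wr = np.array([pset.tf_weights[r.tf_id] for r in pset.records])
        ws = np.array([pset.site_weights[r.site_id] for r in pset.records])
    else:
        wr = pset.weights_array()
        ws = np.ones(pset.n_records)
    return wr, ws


def shuffle_pairings(pset: PairedAlignmentSet, seed: int) -> PairedAlignmentSet:
    """Randomly re-connect TF rows with site rows (one permutation).

    Record k of the result pairs TF k with the site of record pi(k); pair
    weights become w(r_k) * w(s_pi(k)).  The multisets of TF rows and of
    site rows are unchanged.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(pset.n_records)
    wr, ws = _split_weights(pset)
    recs = []
    for k, p in enumerate(perm):
        a, b = pset.records[k], pset.records[p]
        recs.append(
            PairRecord(a.tf_id, b.site_id, a.tf_row, b.site_row, float(wr[k] * ws[p]))
        )
    return PairedAlignmentSet(recs, dict(pset.tf_weights), dict(pset.site_weights))


# ---------------------------------------------------------------------------
# the permutation null


def null_distribution(
    pset: PairedAlignmentSet,
    model: SubstitutionModel,
    n_shuffles: int = 10_000,
    seed: int = 0,
    log_base: float = np.e,
) -> NullModel:
    """Null mean and s.d. of MI per column pair across re-pairings.

    One seeded generator drives the whole sequence of permutations, so the
    null is reproducible bit-for-bit for a given (seed, n_shuffles).
    """
    if n_shuffles < 2:
        raise ValueError("need at least 2 shuffles")
    Po, So = onehot_encodings(pset)
    wr, ws = _split_weights(pset)
    rng = np.random.default_rng(seed)
    R = pset.n_records
    s = None
    s2 = None
    for _ in range(n_shuffles):
        perm = rng.permutation(R)
        w = wr * ws[perm]
        N4 = joint_count_tensor(Po, So[perm], w)
        I, _ = mi_matrix_from_counts(N4, model, log_base)
        if s is None:
            s = I.copy()
            s2 = I ** 2
        else:
            s += I
            s2 += I ** 2
    E = s / n_shuffles
    var = np.maximum(s2 / n_shuffles - E ** 2, 0.0)
    return NullModel(E=E, sd=np.sqrt(var), n_shuffles=n_shuffles, rng_seed=seed)


# ---------------------------------------------------------------------------
# phylogenetic-trace correction


def phylo_trace_correction(
    observed_I: np.ndarray,
    null: NullModel,
    assessable: np.ndarray | None = None,
    bulk_quantile: float = 0.95,
) -> NullModel:
    """Affine re-calibration of the null against the observed bulk.

    Shared ancestry inflates both observed and null MI, but not identically;
    regressing observed I on the raw null mean over the bulk of pairs (the
    top ``1 - bulk_quantile`` fraction of observed I is excluded as
    candidate signal) gives coefficients (alpha, beta).  The corrected null
    is E' = alpha*E + beta, sd' = alpha*sd, with floors alpha >= 1 and
    beta >= 0 so the correction can only widen the null, never manufacture
    significance.
    """
    if observed_I.shape != null.E.shape:
        raise ValueError("observed and null shapes differ")
    mask = np.ones(observed_I.shape, dtype=bool) if assessable is None else assessable.copy()
    obs = observed_I[mask]
    if obs.size >= 10:
        cut = np.quantile(obs, bulk_quantile)
        bulk = mask & (observed_I <= cut)
        x = null.E[bulk]
        y = observed_I[bulk]
        if x.size >= 10 and np.ptp(x) > 0:
            alpha, beta = np.polyfit(x, y, 1)
        else:
            alpha, beta = 1.0, 0.0
    else:
        logger.warning("too few assessable pairs (%d); trace correction skipped", obs.size)
        alpha, beta = 1.0, 0.0
    alpha = max(float(alpha), 1.0)
    beta = max(float(beta), 0.0)
    return NullModel(
        E=null.E, sd=null.sd, n_shuffles=null.n_shuffles, rng_seed=null.rng_seed,
        trace_alpha=alpha, trace_beta=beta,
        E_corrected=alpha * null.E + beta, sd_corrected=alpha * null.sd,
    )


# ---------------------------------------------------------------------------
# Z-scores and the Bernoulli cutoff


def z_score_matrix(
    observed_I: np.ndarray, null: NullModel, assessable: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Z = (I - E') / sd'; pairs with sd' = 0 are marked not assessable."""
    if observed_I.shape != null.E.shape:
        raise ValueError("observed and null shapes differ")
    E = null.effective_E
    sd = null.effective_sd
    ok = sd > 0
    if assessable is not None:
        ok = ok & assessable
    Z = np.full(observed_I.shape, np.nan)
    Z[ok] = (observed_I[ok] - E[ok]) / sd[ok]
    return Z, ok


def bernoulli_cutoff(z_values: np.ndarray) -> tuple[int, np.ndarray]:
    """Select k* minimizing B(k) = P( Binomial(M, p_k) >= k ), p_k = Phi_bar(z_(k)).

    ``z_values`` must be sorted non-increasing.  The curve is evaluated in
    log space (log10), so astronomically small p-values never underflow.
    Returns (k_star, log10_B over k = 1..M); k_star = 0 (nothing selected)
    when even the best B(k) is >= 0.5.

    The argmin is taken over ranks with z_(k) > 0: a pair at or below its
    null expectation cannot be significant, and because permutation MI is
    bounded below (I >= 0), deeply negative Gaussian quantiles never occur,
    which would otherwise make B(k) at k near M spuriously tiny.
    """
    z = np.asarray(z_values, dtype=float)
    if z.size == 0:
        raise ValueError("no Z-scores to threshold")
    if np.any(np.diff(z) > 1e-12):
        raise ValueError("z_values must be sorted in non-increasing order")
    M = z.size
    log_p = norm.logsf(z)       # log upper tail at each z_(k)
    log_q = norm.logcdf(z)      # log(1 - p)
    m = np.arange(M + 1)
    log_binom = gammaln(M + 1) - gammaln(m + 1) - gammaln(M - m + 1)
    log10_B = np.empty(M)
    for k in range(1, M + 1):
        mm = m[k:]
        terms = log_binom[k:] + mm * log_p[k - 1] + (M - mm) * log_q[k - 1]
        log10_B[k - 1] = min(logsumexp(terms) / math.log(10), 0.0)
    n_pos = int(np.sum(z > 0))
    if n_pos == 0:
        return 0, log10_B
    best = int(np.argmin(log10_B[:n_pos]))  # first index on ties -> smallest k
    if log10_B[best] >= LOG10_HALF:
        return 0, log10_B
    return best + 1, log10_B


def rank_pairs(Z: np.ndarray, assessable: np.ndarray) -> list[tuple[int, int, float]]:
    """(j, i, Z) for assessable pairs, Z descending; ties by (j, i)."""
    js, iis = np.nonzero(assessable)
    triples = [(int(j), int(i), float(Z[j, i])) for j, i in zip(js, iis)]
    triples.sort(key=lambda t: (-t[2], t[0], t[1]))
    return triples


def significance_analysis(
    observed_I: np.ndarray,
    null: NullModel,
    assessable: np.ndarray | None = None,
    trace_correction: bool = True,
    provenance: dict | None = None,
) -> CorrelationResult:
    """Trace-correct, score, rank and threshold one observed MI matrix."""
    if trace_correction:
        null = phylo_trace_correction(observed_I, null, assessable)
    Z, ok = z_score_matrix(observed_I, null, assessable)
    ranked = rank_pairs(Z, ok)
    if not ranked:
        raise ValueError("no assessable column pairs")
    zs = np.array([t[2] for t in ranked])
    k_star, curve = bernoulli_cutoff(zs)
    prov = dict(provenance or {})
    prov.update(
        trace_alpha=null.trace_alpha, trace_beta=null.trace_beta,
        n_shuffles=null.n_shuffles, null_seed=null.rng_seed,
    )
    return CorrelationResult(
        Z=Z, assessable=ok, ranked=ranked, log10_B=curve,
        k_star=k_star, selected=ranked[:k_star], provenance=prov,
    )


# ---------------------------------------------------------------------------
# controls and robustness procedures


def negative_control(
    pset: PairedAlignmentSet,
    model: SubstitutionModel,
    seed: int,
    n_shuffles: int = 10_000,
    trace_correction: bool = True,
) -> float:
    """Min log10 B after destroying the TF-site pairing once.

    Shuffled input should lose orders of magnitude of significance relative
    to the intact data; the returned value is the B-cutoff global minimum.
    """
    shuffled = shuffle_pairings(pset, seed)
    I, ok = correlation_matrix(shuffled, model)
    null = null_distribution(shuffled, model, n_shuffles=n_shuffles, seed=seed + 1)
    res = significance_analysis(I, null, ok, trace_correction)
    return res.min_log10_p


def scramble_rows(pset: PairedAlignmentSet, fraction: float, seed: int) -> PairedAlignmentSet:
    """Randomly permute residues within a fraction of protein rows.

    Emulates misalignment / corrupted input: ceil(fraction * n) records are
    chosen at random and each chosen record's amino acids are shuffled
    across its non-gap positions (gaps stay put); site rows are untouched.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = pset.n_records
    k = math.ceil(fraction * n)
    chosen = set(rng.choice(n, size=k, replace=False).tolist()) if k else set()
    recs = []
    for idx, r in enumerate(pset.records):
        if idx in chosen:
            chars = [c for c in r.tf_row if c != GAP]
            perm = rng.permutation(len(chars))
            shuffled = iter([chars[p] for p in perm])
            row = "".join(c if c == GAP else next(shuffled) for c in r.tf_row)
            recs.append(PairRecord(r.tf_id, r.site_id, row, r.site_row, r.weight))
        else:
            recs.append(r)
    return PairedAlignmentSet(recs, dict(pset.tf_weights), dict(pset.site_weights))
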