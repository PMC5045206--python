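"""Weighted counts, pseudocounted frequencies, mutual information, chi-square.

For a protein alignment column i and a site alignment column j the joint
distribution of (amino acid a, nucleotide n) over the weighted TF-site
pairs is summarized by

    I_ij = sum_{a,n} f_ij(a,n) * log( f_ij(a,n) / (f_i(a) f_j(n)) )

in nats, where the frequencies carry kappa*N pseudo-observations spread by
a substitution model: the amino-acid side by BLOSUM-derived P(b -> a), the
nucleotide side uniformly (1/4 each).  Records with a gap at either column
are treated as missing for that column pair.

Two computation routes coexist: per-pair :class:`ColumnPairStats` (explicit
loops, used for contingency reports and as the readable reference) and the
vectorized tensor route used for full matrices and permutation nulls; tests
pin them to each other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignments import AA_ALPHABET, NT_ALPHABET, PairedAlignmentSet
from .substitution import SubstitutionModel

N_AA = 20
N_NT = 4


class DegenerateColumnError(ValueError):
    """No usable (ungapped) records for a column pair."""


# ---------------------------------------------------------------------------
# weighted counts


def weighted_counts(
    pset: PairedAlignmentSet, i: int, j: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Weighted NT-AA pair counts for protein column i, site column j.

    Returns (N_ij [20x4], N_i [20], N_j [4], N_effective); a record with a
    gap at either column is excluded from all four.
    """
    P = pset.protein_matrix()[:, i]
    S = pset.site_matrix()[:, j]
    w = pset.weights_array()
    ok = (P >= 0) & (S >= 0)
    N_ij = np.zeros((N_AA, N_NT))
    np.add.at(N_ij, (P[ok], S[ok]), w[ok])
    return N_ij, N_ij.sum(axis=1), N_ij.sum(axis=0), float(w[ok].sum())


# ---------------------------------------------------------------------------
# pseudocounted frequencies


def positional_frequency(
    N_counts: np.ndarray, N_effective: float, model: SubstitutionModel,
    alphabet: str = "aa",
) -> np.ndarray:
    """Pseudocounted single-column frequencies.

    f_i(a) = [ N_i(a) + kappa * sum_b N_i(b) P(b -> a) ] / ( N (1 + kappa) )

    for amino acids; nucleotides use the uniform model, i.e. a flat
    kappa*N/4 pseudocount per base.
    """
    if N_effective <= 0:
        raise DegenerateColumnError("column has no usable records")
    N_counts = np.asarray(N_counts, dtype=float)
    k = model.kappa
    if alphabet == "aa":
        pseudo = N_counts @ model.P  # sum_b N(b) P[b, a]
    elif alphabet == "nt":
        pseudo = np.full(N_NT, N_counts.sum() / N_NT)
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    return (N_counts + k * pseudo) / (N_effective * (1.0 + k))


def joint_frequency(
    N_ij: np.ndarray, N_i: np.ndarray, N_effective: float, model: SubstitutionModel
) -> np.ndarray:
    """Pseudocounted joint frequencies under independent substitutions.

    f_ij(a,n) = [ N_ij(a,n) + kappa/4 * sum_b P(b -> a) N_i(b) ]
                / ( N (1 + kappa) )

    so that the joint marginalizes exactly to the pseudocounted f_i and f_j.
    """
    if N_effective <= 0:
        raise DegenerateColumnError("column pair has no usable records")
    k = model.kappa
    pseudo = (np.asarray(N_i, dtype=float) @ model.P) / N_NT
    return (np.asarray(N_ij, dtype=float) + k * pseudo[:, None]) / (
        N_effective * (1.0 + k)
    )


# ---------------------------------------------------------------------------
# information measures


def mutual_information(f_ij: np.ndarray, f_i: np.ndarray, f_j: np.ndarray) -> float:
    """Natural-log mutual information; cells with f_ij = 0 contribute 0."""
    f_exp = np.outer(f_i, f_j)
    mask = f_ij > 0
    return float(np.sum(f_ij[mask] * np.log(f_ij[mask] / f_exp[mask])))


def mi_summands(f_ij: np.ndarray, f_i: np.ndarray, f_j: np.ndarray) -> np.ndarray:
    """Per-cell contributions to I_ij (nats); zero cells contribute zero."""
    f_exp = np.outer(f_i, f_j)
    out = np.zeros_like(f_ij)
    mask = f_ij > 0
    out[mask] = f_ij[mask] * np.log(f_ij[mask] / f_exp[mask])
    return out


def chi2_summands(
    N_ij: np.ndarray, N_i: np.ndarray, N_j: np.ndarray, N_effective: float,
    cutoff: float = 50.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-cell Pearson chi-square summands (O-E)^2/E on the weighted counts.

    Returns (summands, sign, highlight): sign is +1 where O > E
    (overrepresented), -1 where O < E, 0 at O = E; highlight marks cells with
    summand >= cutoff.  Cells with E = 0 (hence O = 0) contribute 0.
    """
    if N_effective <= 0:
        raise DegenerateColumnError("column pair has no usable records")
    O = np.asarray(N_ij, dtype=float)
    E = np.outer(N_i, N_j) / N_effective
    summ = np.zeros_like(O)
    mask = E > 0
    summ[mask] = (O[mask] - E[mask]) ** 2 / E[mask]
    sign = np.sign(O - E).astype(int)
    return summ, sign, summ >= cutoff


def column_information_content(f: np.ndarray) -> float:
    """Information content in bits, logo convention: log2|A| + sum f log2 f."""
    f = np.asarray(f, dtype=float)
    nz = f[f > 0]
    return float(np.log2(f.size) + np.sum(nz * np.log2(nz)))


# ---------------------------------------------------------------------------
# per-pair bundle


@dataclass
class ColumnPairStats:
    """All statistics for one (site column j, protein column i) pair."""

    i: int
    j: int
    N_ij: np.ndarray
    N_i: np.ndarray
    N_j: np.ndarray
    N_effective: float
    f_i: np.ndarray
    f_j: np.ndarray
    f_ij: np.ndarray
    I: float
    chi2: np.ndarray
    chi2_sign: np.ndarray
    chi2_highlight: np.ndarray
    mi: np.ndarray

    @property
    def f_exp(self) -> np.ndarray:
        return np.outer(self.f_i, self.f_j)


def column_pair_stats(
    pset: PairedAlignmentSet, i: int, j: int, model: SubstitutionModel,
    chi2_cutoff: float = 50.0,
) -> ColumnPairStats:
    """Compute the full per-pair statistics bundle (reference route)."""
    N_ij, N_i, N_j, N_eff = weighted_counts(pset, i, j)
    if N_eff <= 0:
        raise DegenerateColumnError(f"no usable records for pair (j={j}, i={i})")
    f_i = positional_frequency(N_i, N_eff, model, "aa")
    f_j = positional_frequency(N_j, N_eff, model, "nt")
    f_ij = joint_frequency(N_ij, N_i, N_eff, model)
    I = mutual_information(f_ij, f_i, f_j)
    chi2, sign, hi = chi2_summands(N_ij, N_i, N_j, N_eff, chi2_cutoff)
    return ColumnPairStats(
        i=i, j=j, N_ij=N_ij, N_i=N_i, N_j=N_j, N_effective=N_eff,
        f_i=f_i, f_j=f_j, f_ij=f_ij, I=I, chi2=chi2, chi2_sign=sign,
        chi2_highlight=hi, mi=mi_summands(f_ij, f_i, f_j),
    )


# ---------------------------------------------------------------------------
# vectorized matrix route (shared with the permutation null)


def onehot_encodings(pset: PairedAlignmentSet) -> tuple[np.ndarray, np.ndarray]:
    """One-hot row encodings; gap rows are all-zero, excluding gapped records
    from every count they touch."""
    P = pset.protein_matrix()
    S = pset.site_matrix()
    return _onehot(P, N_AA), _onehot(S, N_NT)


def _onehot(codes: np.ndarray, k: int) -> np.ndarray:
    R, L = codes.shape
    out = np.zeros((R, L, k))
    r, c = np.nonzero(codes >= 0)
    out[r, c, codes[r, c]] = 1.0
    return out


def joint_count_tensor(
    P_onehot: np.ndarray, S_onehot: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Weighted joint counts for every column pair at once.

    Returns N[j, i, a, n] of shape (n_site_cols, n_protein_cols, 20, 4),
    computed as one (Lp*20, R) @ (R, Ls*4) product.
    """
    R, Lp, _ = P_onehot.shape
    _, Ls, _ = S_onehot.shape
    A = (P_onehot * weights[:, None, None]).reshape(R, Lp * N_AA)
    B = S_onehot.reshape(R, Ls * N_NT)
    M = A.T @ B  # (Lp*20, Ls*4)
    return M.reshape(Lp, N_AA, Ls, N_NT).transpose(2, 0, 1, 3)


def mi_matrix_from_counts(
    N4: np.ndarray, model: SubstitutionModel, log_base: float = np.e
) -> tuple[np.ndarray, np.ndarray]:
    """Mutual information for every column pair from the joint count tensor.

    Returns (I, usable): I has shape (n_site_cols, n_protein_cols) in units
    of log ``log_base``; ``usable`` is False where the pair has no ungapped
    records or either column is constant after weighting (MI trivially 0 and
    not assessable).
    """
    k = model.kappa
    N_i = N4.sum(axis=3)          # (Ls, Lp, 20)
    N_j = N4.sum(axis=2)          # (Ls, Lp, 4)
    N_eff = N_i.sum(axis=2)       # (Ls, Lp)
    usable = N_eff > 0
    denom = np.where(usable, N_eff * (1.0 + k), 1.0)[:, :, None, None]

    pseudo_i = N_i @ model.P      # sum_b N_i(b) P[b, a]
    f_ij = (N4 + (k / N_NT) * pseudo_i[:, :, :, None]) / denom
    f_i = (N_i + k * pseudo_i) / denom[:, :, :, 0]
    f_j = (N_j + (k / N_NT) * N_eff[:, :, None]) / denom[:, :, 0, :]

    f_exp = f_i[:, :, :, None] * f_j[:, :, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f_ij > 0, f_ij * np.log(f_ij / f_exp), 0.0)
    I = terms.sum(axis=(2, 3)) / np.log(log_base)
    I[~usable] = 0.0
    constant = ((N_i > 0).sum(axis=2) <= 1) | ((N_j > 0).sum(axis=2) <= 1)
    return I, usable & ~constant


def correlation_matrix(
    pset: PairedAlignmentSet, model: SubstitutionModel, log_base: float = np.e
) -> tuple[np.ndarray, np.ndarray]:
    """I_ij for all pairs; shape (n_site_cols, n_protein_cols).

    The second return value flags assessable pairs (ungapped records exist
    and neither column is constant).
    """
    Po, So = onehot_encodings(pset)
    N4 = joint_count_tensor(Po, So, pset.weights_array())
    return mi_matrix_from_counts(N4, model, log_base)
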