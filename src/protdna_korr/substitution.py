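"""Residue substitution model backing the pseudocount machinery.

Pseudocounts supplement the N observed sequences with kappa*N fictitious
ones whose residues are drawn through a substitution model: P(b -> a) for
amino acids, derived from a BLOSUM matrix, and the uninformative uniform
model P(m -> n) = 1/4 for nucleotides.

Biopython ships BLOSUM matrices as rounded log-odds scores
s(a,b) = scale * log2( q(a,b) / (p(a) p(b)) ).  The target frequencies
q(a,b) are recovered by inverting that relation with background
frequencies obtained as the fixed point of q's own marginals; the
conditional P(b -> a) = q(a,b)/p(b) is then renormalized row-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from .alignments import AA_ALPHABET

# Bit-scale divisor per matrix: entries are scale * log2(odds).
_BLOSUM_SCALES = {"BLOSUM45": 3.0, "BLOSUM50": 3.0, "BLOSUM62": 2.0,
                  "BLOSUM80": 2.0, "BLOSUM90": 2.0}

DEFAULT_BLOSUM = "BLOSUM45"


class SubstitutionModelError(ValueError):
    pass


@dataclass
class SubstitutionModel:
    """Row-stochastic amino-acid transition matrix plus the kappa setting.

    ``P[b, a]`` is the probability that residue b (row, ``AA_ALPHABET``
    order) is replaced by residue a.  The nucleotide side is fixed at the
    uniform 1/4 model.  ``kappa`` regulates pseudocount mass (default 0.5).
    """

    P: np.ndarray
    kappa: float = 0.5
    name: str = DEFAULT_BLOSUM

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.shape != (20, 20):
            raise SubstitutionModelError(f"P must be 20x20, got {P.shape}")
        if np.any(P < 0):
            raise SubstitutionModelError("negative transition probabilities")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise SubstitutionModelError("rows of P must sum to 1")
        if self.kappa < 0:
            raise SubstitutionModelError("kappa must be nonnegative")
        self.P = P


def identity_model(kappa: float = 0.5) -> SubstitutionModel:
    """Identity substitutions: pseudocounts reproduce the observed counts."""
    return SubstitutionModel(np.eye(20), kappa=kappa, name="identity")


def blosum_transition_probs(
    name: str = DEFAULT_BLOSUM, kappa: float = 0.5
) -> SubstitutionModel:
    """Build P(b -> a) from a named BLOSUM matrix.

    q(a,b) is reconstructed from the rounded scores (see module docstring);
    rows of the conditional are renormalized to absorb rounding error.
    """
    name = name.upper()
    if name == "IDENTITY":
        return identity_model(kappa)
    if name not in _BLOSUM_SCALES:
        raise SubstitutionModelError(
            f"unknown matrix {name!r}; choose from {sorted(_BLOSUM_SCALES)} or 'identity'"
        )
    mat = substitution_matrices.load(name)
    scale = _BLOSUM_SCALES[name]
    s = np.array(
        [[mat[a, b] for b in AA_ALPHABET] for a in AA_ALPHABET], dtype=float
    )
    odds = np.power(2.0, s / scale)  # q(a,b) / (p(a) p(b)), up to rounding
    # marginal consistency sum_b q(a,b) = p(a) requires odds @ p = 1;
    # solving that linear system recovers the backgrounds despite rounding
    p = np.linalg.solve(odds, np.ones(20))
    if np.any(p <= 0):
        raise SubstitutionModelError(f"{name}: recovered backgrounds not positive")
    p = p / p.sum()
    # P[b, a] = q(a,b) / p(b) = odds(a,b) * p(a); renormalize rounding residue
    P = odds.T * p[None, :]
    P = P / P.sum(axis=1, keepdims=True)
    return SubstitutionModel(P, kappa=kappa, name=name)
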