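"""Synthetic paired alignments with subfamily structure and planted couplings.

The generator emulates the structure the correlation pipeline is built to
detect: a handful of TF subfamilies (clades), each carrying its own
nucleotide-amino-acid combination at a few "planted" column pairs, on top
of background columns that drift within clades but are independent of the
pairing.  The clade structure creates the shared-ancestry confound that
GSC weighting and the trace correction are meant to absorb; the planted
pairs provide ground truth for recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignments import AA_ALPHABET, NT_ALPHABET, PairRecord, PairedAlignmentSet
from .significance import CorrelationResult

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# coupling palettes cycled over planted pairs; one (nt, aa) per subfamily,
# echoing the kind of clade-specific combinations seen in real TF families
_NT_PALETTE = ["T", "C", "G", "A", "T", "C", "G", "A"]
_AA_PALETTES = [
    ["E", "K", "D", "A", "Q"],
    ["K", "E", "A", "V", "M"],
    ["V", "A", "K", "M", "T"],
    ["M", "T", "E", "R", "S"],
    ["R", "S", "Q", "H", "W"],
    ["A", "Q", "M", "E", "I"],
]


@dataclass(frozen=True)
class PlantedPair:
    """One coupled column pair: site column j, protein column i, and the
    subfamily -> (nucleotide, residue) assignment."""

    j: int
    i: int
    coupling: dict[int, tuple[str, str]]


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults describe the reference fixture: 5 subfamilies x 40 records over
    a 74-column protein block and 20-column sites, 6 planted pairs, 10%
    noise at planted cells.  Background columns drift within a clade with
    per-position redraw probability 0.5 — clade members stay recognizably
    related (the shared-ancestry confound) while background columns remain
    far less clade-determined than the planted, specificity-like columns.
    """

    n_subfamilies: int = 5
    records_per_subfamily: int = 40
    n_protein_cols: int = 74
    n_site_cols: int = 20
    planted_pairs: list[PlantedPair] | None = None
    background_entropy: int = 4     # residue pool size per background column
    noise_rate: float = 0.1
    within_subfamily_divergence: float = 0.5
    dyad_symmetry: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_pairs is None:
            self.planted_pairs = default_planted_pairs(
                self.n_subfamilies, self.n_site_cols, self.n_protein_cols
            )
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must be in [0, 1]")
        if not 0.0 <= self.within_subfamily_divergence <= 1.0:
            raise ValueError("within_subfamily_divergence must be in [0, 1]")
        if self.n_subfamilies < 1 or self.records_per_subfamily < 1:
            raise ValueError("need at least one subfamily and one record")
        if not 1 <= self.background_entropy <= 20:
            raise ValueError("background_entropy must be in 1..20")
        for p in self.planted_pairs:
            if not (0 <= p.j < self.n_site_cols and 0 <= p.i < self.n_protein_cols):
                raise ValueError(f"planted pair ({p.j}, {p.i}) out of range")
            if len(set(p.coupling.values())) < 2 and self.n_subfamilies > 1:
                raise ValueError(
                    f"planted pair ({p.j}, {p.i}) must assign distinct NT-AA "
                    "combinations to at least 2 subfamilies"
                )


def default_planted_pairs(
    n_subfamilies: int, n_site_cols: int, n_protein_cols: int, n_pairs: int = 6
) -> list[PlantedPair]:
    """Six coupled pairs at fixed coordinates.

    Coordinates are column-disjoint (no two planted pairs share a site or a
    protein column): clade-level couplings make every pair of clade-tracking
    columns correlate, so sharing columns between planted pairs would leave
    "which pair is the true one" ambiguous and recovery scoring ill-posed.
    """
    coords = [(6, 14), (13, 21), (3, 13), (5, 15), (8, 35), (16, 5)]
    out = []
    for k, (j, i) in enumerate(coords[:n_pairs]):
        aa = _AA_PALETTES[k % len(_AA_PALETTES)]
        coupling = {
            s: (_NT_PALETTE[(s + k) % len(_NT_PALETTE)], aa[s % len(aa)])
            for s in range(n_subfamilies)
        }
        out.append(
            PlantedPair(j % n_site_cols, i % n_protein_cols, coupling)
        )
    return out


def null_spec(**overrides) -> SyntheticSpec:
    """Fully independent columns: one clade, full per-site redraw, nothing
    planted.  Input for type-I-error experiments."""
    kw = dict(
        n_subfamilies=1,
        records_per_subfamily=200,
        planted_pairs=[],
        within_subfamily_divergence=1.0,
    )
    kw.update(overrides)
    return SyntheticSpec(**kw)


@dataclass
class TruthTable:
    """Ground truth emitted alongside a synthetic dataset."""

    planted: list[tuple[int, int]]            # (j, i)
    subfamily_of: dict[str, int]              # tf_id -> subfamily index

    def to_dict(self) -> dict:
        return {
            "planted_pairs": [list(p) for p in self.planted],
            "subfamily_of": self.subfamily_of,
        }


def generate_coupled_dataset(spec: SyntheticSpec) -> tuple[PairedAlignmentSet, TruthTable]:
    """Draw one dataset under ``spec``; deterministic for a given seed.

    Each subfamily gets an ancestral protein/site sequence; records are
    per-position mutated copies (the clade drift).  Planted column pairs are
    then overwritten with the record's subfamily combination, except with
    probability ``noise_rate`` where nucleotide and residue are drawn
    independently, breaking the association for that record.
    """
    rng = np.random.default_rng(spec.seed)
    planted_cols_p = {p.i for p in spec.planted_pairs}
    planted_cols_s = {p.j for p in spec.planted_pairs}

    # per-column residue pools keep background columns moderately polymorphic
    aa_pools = [
        rng.choice(list(AA_ALPHABET), size=spec.background_entropy, replace=False)
        for _ in range(spec.n_protein_cols)
    ]
    nt_list = list(NT_ALPHABET)

    records: list[PairRecord] = []
    subfamily_of: dict[str, int] = {}
    for s in range(spec.n_subfamilies):
        anc_p = [rng.choice(aa_pools[c]) for c in range(spec.n_protein_cols)]
        anc_s = [rng.choice(nt_list) for c in range(spec.n_site_cols)]
        for k in range(spec.records_per_subfamily):
            prot = list(anc_p)
            site = list(anc_s)
            for c in range(spec.n_protein_cols):
                if rng.random() < spec.within_subfamily_divergence:
                    prot[c] = rng.choice(aa_pools[c])
            for c in range(spec.n_site_cols):
                if rng.random() < spec.within_subfamily_divergence:
                    site[c] = rng.choice(nt_list)
            for p in spec.planted_pairs:
                nt, aa = p.coupling[s % len(p.coupling)]
                if rng.random() < spec.noise_rate:
                    nts = sorted({v[0] for v in p.coupling.values()})
                    aas = sorted({v[1] for v in p.coupling.values()})
                    site[p.j] = nts[rng.integers(len(nts))]
                    prot[p.i] = aas[rng.integers(len(aas))]
                else:
                    site[p.j] = nt
                    prot[p.i] = aa
            if spec.dyad_symmetry:
                L = spec.n_site_cols
                for j in range(L // 2):
                    jp = L - 1 - j
                    if j in planted_cols_s or jp in planted_cols_s:
                        continue
                    site[jp] = _COMPLEMENT[site[j]]
            tf_id = f"sf{s}_tf{k}"
            site_id = f"sf{s}_site{k}"
            subfamily_of[tf_id] = s
            records.append(PairRecord(tf_id, site_id, "".join(prot), "".join(site)))

    truth = TruthTable(
        planted=[(p.j, p.i) for p in spec.planted_pairs], subfamily_of=subfamily_of
    )
    return PairedAlignmentSet(records), truth


def recovery_report(
    result: CorrelationResult, truth: TruthTable
) -> tuple[float, float, dict[tuple[int, int], int | None]]:
    """Precision/recall of the selected pairs against the planted ones,
    plus the rank of each planted pair in the Z ordering (1-based; None if
    the pair was not assessable)."""
    selected = {(j, i) for j, i, _ in result.selected}
    planted = set(truth.planted)
    ranks: dict[tuple[int, int], int | None] = {}
    order = {(j, i): r + 1 for r, (j, i, _) in enumerate(result.ranked)}
    for p in truth.planted:
        ranks[p] = order.get(p)
    tp = len(selected & planted)
    precision = tp / len(selected) if selected else (1.0 if not planted else 0.0)
    recall = tp / len(planted) if planted else 1.0
    return precision, recall, ranks
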