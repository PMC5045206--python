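"""Paired TF / binding-site alignment container and its readers and writers.

The central object is :class:`PairedAlignmentSet`: one row per TF-site pair,
holding the gapped amino-acid row of the transcription factor's DNA-binding
domain and the gapped nucleotide row of its binding site, plus the sequence
weights used throughout the correlation statistics.  A TF may pair with
several sites (and vice versa), so pairing is supplied as an explicit table
rather than inferred from record order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NT_ALPHABET = "ACGT"
GAP = "-"

AA_INDEX = {c: k for k, c in enumerate(AA_ALPHABET)}
NT_INDEX = {c: k for k, c in enumerate(NT_ALPHABET)}


class AlignmentShapeError(ValueError):
    """Rows of one alignment differ in length."""


class AlphabetError(ValueError):
    """A sequence contains a character outside its alphabet (gaps excepted)."""


class PairingReferenceError(KeyError):
    """A pairing row names an id absent from the corresponding FASTA."""


@dataclass(frozen=True)
class PairRecord:
    """One TF-site observation: a row of each alignment plus its weight."""

    tf_id: str
    site_id: str
    tf_row: str
    site_row: str
    weight: float = 1.0


@dataclass
class PairedAlignmentSet:
    """Parallel TF / site alignment rows with per-pair weights.

    ``tf_weights`` and ``site_weights`` map sequence ids to the individual
    sequence weights w(r) and w(s); each record's pair weight is their
    product w(rs) = w(r) x w(s).  ``total_weight`` (N) is the summed pair
    weight, the effective number of observations entering the weighted
    column counts.
    """

    records: list[PairRecord]
    tf_weights: dict[str, float] = field(default_factory=dict)
    site_weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- basic geometry ----------------------------------------------------

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_protein_cols(self) -> int:
        return len(self.records[0].tf_row) if self.records else 0

    @property
    def n_site_cols(self) -> int:
        return len(self.records[0].site_row) if self.records else 0

    @property
    def total_weight(self) -> float:
        return float(sum(r.weight for r in self.records))

    def validate(self) -> None:
        if not self.records:
            return
        lp = len(self.records[0].tf_row)
        ls = len(self.records[0].site_row)
        for r in self.records:
            if len(r.tf_row) != lp or len(r.site_row) != ls:
                raise AlignmentShapeError(
                    f"ragged alignment at pair ({r.tf_id}, {r.site_id})"
                )
            _check_alphabet(r.tf_row, AA_INDEX, r.tf_id, "protein")
            _check_alphabet(r.site_row, NT_INDEX, r.site_id, "nucleotide")
            if r.weight < 0:
                raise ValueError(f"negative weight on ({r.tf_id}, {r.site_id})")

    # -- numeric views -----------------------------------------------------

    def protein_matrix(self) -> np.ndarray:
        """Integer-encoded protein rows, shape (n_records, n_protein_cols).

        Amino acids map to 0..19 in ``AA_ALPHABET`` order; gaps to -1.
        """
        return _encode([r.tf_row for r in self.records], AA_INDEX)

    def site_matrix(self) -> np.ndarray:
        """Integer-encoded site rows (A,C,G,T -> 0..3; gap -> -1)."""
        return _encode([r.site_row for r in self.records], NT_INDEX)

    def weights_array(self) -> np.ndarray:
        return np.array([r.weight for r in self.records], dtype=float)

    def with_weights(
        self, tf_weights: dict[str, float], site_weights: dict[str, float]
    ) -> "PairedAlignmentSet":
        """Return a copy with pair weights w(rs) = w(r) x w(s)."""
        recs = []
        for r in self.records:
            if r.tf_id not in tf_weights:
                raise PairingReferenceError(f"no TF weight for {r.tf_id!r}")
            if r.site_id not in site_weights:
                raise PairingReferenceError(f"no site weight for {r.site_id!r}")
            recs.append(replace(r, weight=tf_weights[r.tf_id] * site_weights[r.site_id]))
        return PairedAlignmentSet(recs, dict(tf_weights), dict(site_weights))


def _check_alphabet(row: str, index: dict[str, int], rec_id: str, kind: str) -> None:
    for c in row:
        if c != GAP and c not in index:
            raise AlphabetError(f"invalid {kind} character {c!r} in {rec_id!r}")


def _encode(rows: list[str], index: dict[str, int]) -> np.ndarray:
    out = np.full((len(rows), len(rows[0]) if rows else 0), -1, dtype=np.int8)
    for k, row in enumerate(rows):
        for j, c in enumerate(row):
            if c != GAP:
                out[k, j] = index[c]
    return out


# ---------------------------------------------------------------------------
# readers / writers


def read_fasta_alignment(path) -> dict[str, str]:
    """Read a gapped FASTA alignment into an ordered id -> row mapping.

    Sequences are uppercased; duplicate ids are an error (pairing integrity
    depends on unambiguous ids).
    """
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        rows[rec.id] = str(rec.seq).upper()
    if not rows:
        raise ValueError(f"no FASTA records in {path}")
    lengths = {len(s) for s in rows.values()}
    if len(lengths) > 1:
        raise AlignmentShapeError(f"ragged alignment in {path}: lengths {sorted(lengths)}")
    return rows


def read_pairing_table(path) -> list[tuple[str, str]]:
    """Read a two-column TSV of (tf_id, site_id); '#' comments allowed."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            pairs.append((fields[0], fields[1]))
    return pairs


def read_paired_alignments(tf_fasta, site_fasta, pairing_table) -> PairedAlignmentSet:
    """Assemble a :class:`PairedAlignmentSet` from two FASTAs and a pairing TSV.

    One record per pairing row, uniform weight 1.0 (weighting is a later
    stage).  Unknown ids in the pairing table raise
    :class:`PairingReferenceError`.
    """
    tf_rows = read_fasta_alignment(tf_fasta)
    site_rows = read_fasta_alignment(site_fasta)
    records = []
    for tf_id, site_id in read_pairing_table(pairing_table):
        if tf_id not in tf_rows:
            raise PairingReferenceError(f"pairing table names unknown TF {tf_id!r}")
        if site_id not in site_rows:
            raise PairingReferenceError(f"pairing table names unknown site {site_id!r}")
        records.append(PairRecord(tf_id, site_id, tf_rows[tf_id], site_rows[site_id]))
    return PairedAlignmentSet(records)


def write_paired_alignments(pset: PairedAlignmentSet, tf_fasta, site_fasta, pairing_table) -> None:
    """Write the set back out as two FASTAs plus the pairing TSV."""
    tf_seen: dict[str, str] = {}
    site_seen: dict[str, str] = {}
    for r in pset.records:
        tf_seen.setdefault(r.tf_id, r.tf_row)
        site_seen.setdefault(r.site_id, r.site_row)
    SeqIO.write(
        [SeqRecord(Seq(s), id=i, description="") for i, s in tf_seen.items()],
        str(tf_fasta), "fasta",
    )
    SeqIO.write(
        [SeqRecord(Seq(s), id=i, description="") for i, s in site_seen.items()],
        str(site_fasta), "fasta",
    )
    with open(pairing_table, "w") as fh:
        fh.write("# tf_id\tsite_id\n")
        for r in pset.records:
            fh.write(f"{r.tf_id}\t{r.site_id}\n")


def deduplicate_pairs(pset: PairedAlignmentSet) -> PairedAlignmentSet:
    """Drop records whose (tf_row, site_row) string pair repeats.

    The first occurrence is retained and input order is otherwise preserved;
    redundant identical pairs would otherwise inflate the weighted counts.
    """
    seen: set[tuple[str, str]] = set()
    kept = []
    for r in pset.records:
        key = (r.tf_row, r.site_row)
        if key not in seen:
            seen.add(key)
            kept.append(r)
    return PairedAlignmentSet(kept, dict(pset.tf_weights), dict(pset.site_weights))
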