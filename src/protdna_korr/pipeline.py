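"""Pipeline orchestration and result artifacts.

``run_correlation_pipeline`` chains the full analysis — read, deduplicate,
weight, observed MI, permutation null, trace correction, Z-scores,
Bernoulli cutoff — and writes the artifact set (results.json, heatmap.tsv,
B-curve.tsv, per-selected-pair contingency reports) into a run directory.
Helper analyses (contact enrichment, conservation-vs-Z) live here too.

Coordinate conventions in every output: protein columns are 1-based over
the alignment block; site columns are 0-based, so dyad-symmetric partners
of a 20-column site sum to 19.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import hypergeom

from .alignments import (
    AA_ALPHABET,
    NT_ALPHABET,
    PairedAlignmentSet,
    deduplicate_pairs,
    read_paired_alignments,
)
from .corrstats import column_information_content, column_pair_stats, correlation_matrix
from .significance import (
    CorrelationResult,
    null_distribution,
    significance_analysis,
)
from .substitution import DEFAULT_BLOSUM, blosum_transition_probs
from .weights import weight_paired_set

logger = logging.getLogger(__name__)

HEADER = (
    "# protein columns 1-based over the alignment block; "
    "site columns 0-based (dyad partners of a 20-column site sum to 19)\n"
)


@dataclass
class RunConfig:
    """Everything needed to reproduce one correlation run."""

    tf_fasta: str
    site_fasta: str
    pairing_table: str
    out_dir: str
    kappa: float = 0.5
    blosum: str = DEFAULT_BLOSUM
    n_shuffles: int = 10_000
    seed: int = 0
    tf_weights_mode: str = "gsc"       # gsc | uniform
    site_weights_mode: str = "gsc"     # gsc | uniform
    trace_correction: bool = True
    chi2_cutoff: float = 50.0
    tf_tree: str | None = None      # Newick; bypasses internal NJ for TFs
    site_tree: str | None = None    # Newick; bypasses internal NJ for sites

    def validate(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be nonnegative")
        if self.n_shuffles < 2:
            raise ValueError("need at least 2 shuffles")
        for mode in (self.tf_weights_mode, self.site_weights_mode):
            if mode not in ("gsc", "uniform"):
                raise ValueError(f"unknown weights mode {mode!r}")


def analyze_paired_set(
    pset: PairedAlignmentSet,
    kappa: float = 0.5,
    blosum: str = DEFAULT_BLOSUM,
    n_shuffles: int = 1000,
    seed: int = 0,
    tf_weights_mode: str = "gsc",
    site_weights_mode: str = "gsc",
    trace_correction: bool = True,
    tf_tree=None,
    site_tree=None,
) -> tuple[CorrelationResult, np.ndarray, PairedAlignmentSet]:
    """In-memory pipeline core: weight -> MI -> null -> Z -> B-cutoff.

    Returns (result, observed MI matrix, weighted set).  ``seed`` drives the
    permutation null; identical inputs and seed reproduce the result
    exactly.  Supplied :class:`~protdna_korr.trees.PhyloTree` objects bypass
    the internal NJ construction for that side.
    """
    model = blosum_transition_probs(blosum, kappa)
    pset = deduplicate_pairs(pset)
    weighted = weight_paired_set(
        pset, site_weights_mode, tf_weights_mode, tf_tree=tf_tree, site_tree=site_tree
    )
    I, ok = correlation_matrix(weighted, model)
    null = null_distribution(weighted, model, n_shuffles=n_shuffles, seed=seed)
    result = significance_analysis(
        I, null, ok, trace_correction,
        provenance={
            "kappa": kappa, "blosum": model.name, "seed": seed,
            "tf_weights": tf_weights_mode, "site_weights": site_weights_mode,
            "trace_correction": trace_correction,
            "n_records": pset.n_records, "total_weight": weighted.total_weight,
        },
    )
    return result, I, weighted


def run_correlation_pipeline(config: RunConfig) -> CorrelationResult:
    """File-to-file pipeline: read inputs, analyze, write all artifacts."""
    config.validate()
    logger.info("reading paired alignments: %s / %s", config.tf_fasta, config.site_fasta)
    pset = read_paired_alignments(
        config.tf_fasta, config.site_fasta, config.pairing_table
    )
    if not pset.records:
        raise ValueError("pairing table is empty")
    before = pset.n_records
    pset = deduplicate_pairs(pset)
    logger.info("deduplicated %d -> %d pairs", before, pset.n_records)
    from .trees import PhyloTree

    tf_tree = (
        PhyloTree.from_newick(Path(config.tf_tree).read_text())
        if config.tf_tree else None
    )
    site_tree = (
        PhyloTree.from_newick(Path(config.site_tree).read_text())
        if config.site_tree else None
    )
    result, I, weighted = analyze_paired_set(
        pset,
        kappa=config.kappa,
        blosum=config.blosum,
        n_shuffles=config.n_shuffles,
        seed=config.seed,
        tf_weights_mode=config.tf_weights_mode,
        site_weights_mode=config.site_weights_mode,
        trace_correction=config.trace_correction,
        tf_tree=tf_tree,
        site_tree=site_tree,
    )
    logger.info(
        "B-cutoff selected k*=%d pairs (min log10 p = %.2f)",
        result.k_star, result.min_log10_p,
    )
    write_artifacts(Path(config.out_dir), config, result, I, weighted)
    return result


# ---------------------------------------------------------------------------
# artifact writers


def write_artifacts(
    out_dir: Path,
    config: RunConfig,
    result: CorrelationResult,
    observed_I: np.ndarray,
    weighted: PairedAlignmentSet,
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "results.json").write_text(results_json(config, result, observed_I))
    (out_dir / "heatmap.tsv").write_text(heatmap_tsv(result))
    (out_dir / "B-curve.tsv").write_text(b_curve_tsv(result))
    model = blosum_transition_probs(config.blosum, config.kappa)
    for j, i, _ in result.selected:
        stats = column_pair_stats(weighted, i, j, model, config.chi2_cutoff)
        path = out_dir / f"contingency_j{j}_i{i + 1}.txt"
        path.write_text(contingency_report(stats))


def results_json(
    config: RunConfig, result: CorrelationResult, observed_I: np.ndarray
) -> str:
    pairs = [
        {
            "j": j, "i": i + 1, "I": round(float(observed_I[j, i]), 12),
            "Z": round(z, 12),
        }
        for j, i, z in result.ranked
    ]
    doc = {
        "config": asdict(config),
        "provenance": result.provenance,
        "k_star": result.k_star,
        "min_log10_p": round(result.min_log10_p, 6),
        "selected": [{"j": j, "i": i + 1, "Z": round(z, 12)} for j, i, z in result.selected],
        "ranked": pairs,
        "log10_B": [round(float(v), 6) for v in result.log10_B],
    }
    return json.dumps(doc, indent=1, sort_keys=True) + "\n"


def heatmap_tsv(result: CorrelationResult) -> str:
    """Z matrix, site rows x protein columns; non-assessable pairs as NA."""
    Ls, Lp = result.Z.shape
    lines = [HEADER.rstrip("\n")]
    lines.append("site\\protein\t" + "\t".join(str(i + 1) for i in range(Lp)))
    for j in range(Ls):
        cells = [
            f"{result.Z[j, i]:.4f}" if result.assessable[j, i] else "NA"
            for i in range(Lp)
        ]
        lines.append(f"{j}\t" + "\t".join(cells))
    return "\n".join(lines) + "\n"


def b_curve_tsv(result: CorrelationResult) -> str:
    lines = ["k\tlog10_B"]
    for k, v in enumerate(result.log10_B, start=1):
        lines.append(f"{k}\t{v:.6f}")
    return "\n".join(lines) + "\n"


def contingency_report(stats) -> str:
    """Plain-text NT-AA contingency table with chi2 and MI summand blocks.

    Overrepresented highlighted cells are marked '+', underrepresented '-'
    (chi2 summand >= cutoff).
    """
    def block(title: str, table: np.ndarray, marks: np.ndarray | None = None) -> list[str]:
        lines = [title, "AA\\NT\t" + "\t".join(NT_ALPHABET)]
        for a, aa in enumerate(AA_ALPHABET):
            row = []
            for n in range(len(NT_ALPHABET)):
                cell = f"{table[a, n]:.4f}"
                if marks is not None and marks[a, n]:
                    cell += "+" if stats.chi2_sign[a, n] > 0 else "-"
                row.append(cell)
            lines.append(f"{aa}\t" + "\t".join(row))
        return lines

    lines = [
        HEADER.rstrip("\n"),
        f"# pair (j={stats.j}, i={stats.i + 1}), N_effective={stats.N_effective:.4f}, "
        f"I={stats.I:.6f} nats",
        "",
    ]
    lines += block("## weighted counts N_ij(a,n)", stats.N_ij)
    lines.append("")
    lines += block("## chi2 summands (O-E)^2/E", stats.chi2, stats.chi2_highlight)
    lines.append("")
    lines += block("## MI summands (nats)", stats.mi)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# companion analyses


def contact_enrichment_test(
    selected_pairs: set[tuple[int, int]],
    contact_pairs: set[tuple[int, int]],
    total_pairs: int,
) -> tuple[int, float]:
    """Overlap of correlated and structurally contacting pairs.

    One-sided Fisher exact test (hypergeometric upper tail) on the 2x2
    table over a universe of ``total_pairs`` column pairs: probability of
    an overlap at least as large under random draws.
    """
    k = len(selected_pairs & contact_pairs)
    n_sel, n_con = len(selected_pairs), len(contact_pairs)
    if n_sel > total_pairs or n_con > total_pairs:
        raise ValueError("set sizes exceed the universe")
    p = float(hypergeom.sf(k - 1, total_pairs, n_con, n_sel))
    return k, p


def conservation_vs_z_table(
    result: CorrelationResult, weighted: PairedAlignmentSet, kappa: float = 0.5,
    blosum: str = DEFAULT_BLOSUM,
) -> str:
    """TSV of (i, j, protein-column information content, Z, selected flag).

    IC is computed from the weighted, pseudocounted protein column
    frequencies (bits); one row per assessable pair.
    """
    from .corrstats import positional_frequency, weighted_counts

    model = blosum_transition_probs(blosum, kappa)
    selected = {(j, i) for j, i, _ in result.selected}
    lines = [HEADER.rstrip("\n"), "i\tj\tIC_bits\tZ\tselected"]
    ic_cache: dict[tuple[int, int], float] = {}
    for j, i, z in result.ranked:
        _, N_i, _, N_eff = weighted_counts(weighted, i, j)
        f_i = positional_frequency(N_i, N_eff, model, "aa")
        ic = column_information_content(f_i)
        flag = 1 if (j, i) in selected else 0
        lines.append(f"{i + 1}\t{j}\t{ic:.4f}\t{z:.4f}\t{flag}")
    return "\n".join(lines) + "\n"
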