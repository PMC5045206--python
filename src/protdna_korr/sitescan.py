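"""PWM scanning of upstream regions with sigma70 promoter co-localization.

MerR-family activators bind between the -35 and -10 boxes of unusually
long-spacered sigma70 promoters, which gives a geometric filter for weeding
out false-positive PWM hits: a credible site must overlap a promoter whose
hexamer spacer is 19-20 bp, with the distance between the site center and
the 3' end of the -35 box fixed by the site length (7 bp for 21-bp sites,
8 bp for 22-bp sites).

Coordinates are 0-based half-open on the forward strand throughout.  PWM
scores are additive log2-odds; score thresholds are dialect-specific and
accepted as plain floats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignments import NT_INDEX

MINUS35 = "TTGACA"
MINUS10 = "TATAAT"


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class PwmError(ValueError):
    pass


@dataclass
class Pwm:
    """Per-position log2-odds over A, C, G, T."""

    log_odds: np.ndarray            # (L, 4)
    background: np.ndarray
    pseudocount: float

    @property
    def width(self) -> int:
        return self.log_odds.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    def score(self, window: str) -> float:
        idx = [NT_INDEX[c] for c in window]
        return float(self.log_odds[np.arange(self.width), idx].sum())


def build_pwm(
    sites: list[str], background: np.ndarray | None = None, pseudocount: float = 0.5
) -> Pwm:
    """Log-odds PWM from equal-length ACGT site sequences.

    entry(l, n) = log2( (count + pseudocount) / (n_sites + 4*pseudocount)
                        / background(n) ).
    """
    if len(sites) < 2:
        raise PwmError("need at least 2 sites")
    L = len(sites[0])
    if any(len(s) != L for s in sites):
        raise PwmError("sites must have identical length")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    counts = np.zeros((L, 4))
    for s in sites:
        for pos, c in enumerate(s.upper()):
            if c not in NT_INDEX:
                raise PwmError(f"non-ACGT character {c!r}")
            counts[pos, NT_INDEX[c]] += 1.0
    freq = (counts + pseudocount) / (len(sites) + 4 * pseudocount)
    return Pwm(np.log2(freq / bg[None, :]), bg, pseudocount)


@dataclass(frozen=True)
class SiteCall:
    """One PWM hit; ``start`` is 0-based on the forward strand, end = start + L."""

    contig: str
    start: int
    strand: str
    score: float
    length: int
    passed_promoter_filter: bool = False
    promoter: tuple[int, int] | None = None   # (-35 box start, -10 box start)

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def center(self) -> float:
        return self.start + (self.length - 1) / 2.0


@dataclass
class PromoterGeometry:
    """sigma70 consensus boxes and the MerR-type spacing rules."""

    minus35: str = MINUS35
    minus10: str = MINUS10
    spacer_range: tuple[int, int] = (19, 20)
    max_mismatch_per_box: int = 2
    center_to_minus35_distance: dict[int, int] = field(
        default_factory=lambda: {21: 7, 22: 8}
    )


@dataclass(frozen=True)
class PromoterCall:
    """A candidate promoter placement (coordinates of both boxes, forward
    strand, 0-based half-open; ``strand`` tells which strand the consensus
    reads on)."""

    contig: str
    minus35_start: int
    minus10_start: int
    spacer: int
    strand: str

    def minus35_three_prime(self) -> int:
        """Position (0-based) of the last base of the -35 box on its strand."""
        if self.strand == "+":
            return self.minus35_start + len(MINUS35) - 1
        return self.minus35_start


def scan_upstream(
    sequence: str,
    gene_start: int,
    pwm: Pwm,
    threshold: float,
    contig: str = "contig",
    upstream: int = 400,
    downstream: int = 50,
) -> list[SiteCall]:
    """Scan [gene_start - upstream, gene_start + downstream) on both strands.

    Every window scoring >= threshold is reported; coordinates refer to the
    forward strand regardless of the hit strand.
    """
    seq = sequence.upper()
    lo = max(0, gene_start - upstream)
    hi = min(len(seq), gene_start + downstream)
    L = pwm.width
    calls = []
    for start in range(lo, hi - L + 1):
        window = seq[start : start + L]
        if any(c not in NT_INDEX for c in window):
            continue
        for strand, w in (("+", window), ("-", reverse_complement(window))):
            s = pwm.score(w)
            if s >= threshold:
                calls.append(SiteCall(contig, start, strand, s, L))
    return calls


def _mismatches(window: str, consensus: str) -> int:
    return sum(1 for a, b in zip(window, consensus) if a != b)


def find_sigma70_promoters(
    sequence: str, geometry: PromoterGeometry | None = None, contig: str = "contig"
) -> list[PromoterCall]:
    """All TTGACA-(spacer)-TATAAT placements within the mismatch budget.

    Both strands are searched; reported coordinates are forward-strand.
    """
    geo = geometry or PromoterGeometry()
    seq = sequence.upper()
    out = []
    for strand in ("+", "-"):
        s = seq if strand == "+" else reverse_complement(seq)
        n = len(s)
        l35, l10 = len(geo.minus35), len(geo.minus10)
        for p35 in range(n - l35 + 1):
            if _mismatches(s[p35 : p35 + l35], geo.minus35) > geo.max_mismatch_per_box:
                continue
            for spacer in range(geo.spacer_range[0], geo.spacer_range[1] + 1):
                p10 = p35 + l35 + spacer
                if p10 + l10 > n:
                    continue
                if _mismatches(s[p10 : p10 + l10], geo.minus10) > geo.max_mismatch_per_box:
                    continue
                if strand == "+":
                    out.append(PromoterCall(contig, p35, p10, spacer, "+"))
                else:
                    # map back to forward-strand coordinates
                    f35 = n - (p35 + l35)
                    f10 = n - (p10 + l10)
                    out.append(PromoterCall(contig, f35, f10, spacer, "-"))
    return out


def promoter_colocalization_filter(
    calls: list[SiteCall],
    promoters: list[PromoterCall],
    geometry: PromoterGeometry | None = None,
) -> list[SiteCall]:
    """Mark each site call as passing iff some promoter satisfies the rules.

    A call passes when a promoter has spacer within the allowed range and
    the distance between the site center and the 3' end of the -35 box
    equals the value mapped from the site length (fractional centers are
    rounded half-up).  Pure per-call predicate: order-independent.
    """
    geo = geometry or PromoterGeometry()
    out = []
    for call in calls:
        if call.length not in geo.center_to_minus35_distance:
            raise PwmError(
                f"no center-to-(-35) distance configured for length {call.length}"
            )
        want = geo.center_to_minus35_distance[call.length]
        hit = None
        for prom in promoters:
            if prom.contig != call.contig:
                continue
            if not geo.spacer_range[0] <= prom.spacer <= geo.spacer_range[1]:
                continue
            dist = abs(call.center - prom.minus35_three_prime())
            if int(np.floor(dist + 0.5)) == want:
                hit = prom
                break
        out.append(
            SiteCall(
                call.contig, call.start, call.strand, call.score, call.length,
                passed_promoter_filter=hit is not None,
                promoter=(hit.minus35_start, hit.minus10_start) if hit else None,
            )
        )
    return out
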