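"""QTL confirmation with near-isogenic lines (NILs).

A NIL carries one or more small donor-genome (allele B) introgressions in
an otherwise uniform recurrent-parent (allele A) background.  A significant trait difference between a NIL and the recurrent
background is attributed to a causal allele inside an introgression, which
confirms a mapped QTL when the introgression covers the QTL interval and
the effect has the expected direction.

Direction logic: the mapped additive effect ADD is the A-allele effect
relative to the population mean, while an introgression replaces A by B, so
a QTL with ADD > 0 predicts a *down* effect in the covering NIL and vice
versa (expected direction = -sign(ADD)).

Border refinement: the confirmed interval is the intersection of the QTL
interval with the union of the confirming introgressions, minus the
introgressions of covering NILs that showed no effect — the same exclusion
logic that narrows a locus when nested introgressions disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .popstats import welch_test
from .qtlmap import QTLCall

__all__ = ["NILDefinition", "EffectCall", "ConfirmationResult",
           "classify_effect", "confirm_qtl", "extra_qtl_screen"]

Interval = tuple[float, float]


@dataclass(frozen=True)
class NILDefinition:
    """A NIL and its donor introgressions as (chromosome, start, end) in cM."""

    nil_id: str
    introgressions: tuple  # of (chrom, start_cM, end_cM)
    map_name: Optional[str] = None

    def __post_init__(self):
        per_chrom: dict = {}
        for (c, s, e) in self.introgressions:
            if e <= s:
                raise ValueError(f"degenerate introgression ({c}, {s}, {e})")
            per_chrom.setdefault(c, []).append((s, e))
        for c, ivs in per_chrom.items():
            ivs.sort()
            for (a, b), (x, y) in zip(ivs, ivs[1:]):
                if x <= b:
                    raise ValueError(f"overlapping introgressions on chromosome {c!r}")

    def on_chromosome(self, chrom) -> list[Interval]:
        return sorted((s, e) for (c, s, e) in self.introgressions if c == chrom)


@dataclass(frozen=True)
class EffectCall:
    """NIL-vs-background comparison for one trait.

    direction: 'up' / 'down' / 'none'; level: 'strong' (P < 0.01),
    'weak' (0.01 <= P < 0.05) or 'ns'.
    """

    nil_id: str
    trait: str
    direction: str
    level: str
    t: float = float("nan")
    p_value: float = float("nan")

    def __post_init__(self):
        if (self.direction == "none") != (self.level == "ns"):
            raise ValueError("direction 'none' must pair with level 'ns'")

    @property
    def significant(self) -> bool:
        return self.level in ("strong", "weak")


@dataclass(frozen=True)
class ConfirmationResult:
    qtl: QTLCall
    status: str                       # confirmed / not_confirmed / not_covered / opposite_sign
    explaining_nils: tuple = ()
    refined_interval: Optional[Interval] = None
    refined_segments: tuple = ()


def classify_effect(nil_values, background_values, trait: str,
                    nil_id: str = "NIL") -> EffectCall:
    """Welch-test a NIL against the recurrent background for one trait."""
    if len(nil_values) < 3 or len(background_values) < 3:
        raise ValueError("need at least 3 values per group")
    t, p, sign = welch_test(nil_values, background_values)
    if p < 0.01:
        level = "strong"
    elif p < 0.05:
        level = "weak"
    else:
        level = "ns"
    if level == "ns" or sign == 0:
        return EffectCall(nil_id, trait, "none", "ns", t, p)
    return EffectCall(nil_id, trait, "up" if sign > 0 else "down", level, t, p)


def _intersect(a: Interval, b: Interval) -> Optional[Interval]:
    lo, hi = max(a[0], b[0]), min(a[1], b[1])
    return (lo, hi) if lo < hi else None


def _subtract(segments: list[Interval], cut: Interval) -> list[Interval]:
    out = []
    for (s, e) in segments:
        if cut[1] <= s or cut[0] >= e:
            out.append((s, e))
            continue
        if s < cut[0]:
            out.append((s, cut[0]))
        if cut[1] < e:
            out.append((cut[1], e))
    return out


def _lookup_effect(effect_calls: Sequence[EffectCall], nil_id: str, trait) -> Optional[EffectCall]:
    for e in effect_calls:
        if e.nil_id == nil_id and (trait is None or e.trait == trait):
            return e
    return None


def confirm_qtl(qtl_call: QTLCall, qtl_sign: int, nils: Sequence[NILDefinition],
                effect_calls: Sequence[EffectCall]) -> ConfirmationResult:
    """Confront a QTL call with a NIL panel.

    * not_covered: no introgression intersects the QTL interval;
    * confirmed: at least one covering NIL shows a significant effect (any
      level) in the expected direction (-sign(ADD)); the refined interval is
      QTL-interval ∩ union(confirming introgressions) minus the
      introgressions of covering NILs without an effect;
    * opposite_sign: covering NILs show significant effects, all opposite;
    * not_confirmed: covered, but no covering NIL shows any effect.
    """
    for nil in nils:
        if nil.map_name is not None and qtl_call.map_name is not None \
                and nil.map_name != qtl_call.map_name:
            raise ValueError(f"NIL {nil.nil_id} and QTL call use different maps")
    interval = (qtl_call.start, qtl_call.end)
    expected = "down" if qtl_sign > 0 else "up"

    covering = []
    for nil in nils:
        ivs = [iv for iv in nil.on_chromosome(qtl_call.chrom)
               if max(iv[0], interval[0]) <= min(iv[1], interval[1])]
        if ivs:
            covering.append((nil, ivs))
    if not covering:
        return ConfirmationResult(qtl_call, "not_covered")

    confirming, ns_covering, opposite = [], [], []
    for nil, ivs in covering:
        eff = _lookup_effect(effect_calls, nil.nil_id, qtl_call.trait)
        if eff is None or not eff.significant:
            ns_covering.append((nil, ivs))
        elif eff.direction == expected:
            confirming.append((nil, ivs))
        else:
            opposite.append((nil, ivs))

    if confirming:
        segments: list[Interval] = []
        for nil, _ in confirming:
            for iv in nil.on_chromosome(qtl_call.chrom):
                x = _intersect(iv, interval)
                if x:
                    segments.append(x)
        segments.sort()
        merged: list[Interval] = []
        for seg in segments:
            if merged and seg[0] <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], seg[1]))
            else:
                merged.append(seg)
        for nil, _ in ns_covering:
            for iv in nil.on_chromosome(qtl_call.chrom):
                merged = _subtract(merged, iv)
        refined = (merged[0][0], merged[-1][1]) if merged else None
        return ConfirmationResult(qtl_call, "confirmed",
                                  explaining_nils=tuple(n.nil_id for n, _ in confirming),
                                  refined_interval=refined,
                                  refined_segments=tuple(merged))
    if opposite:
        return ConfirmationResult(qtl_call, "opposite_sign",
                                  explaining_nils=tuple(n.nil_id for n, _ in opposite))
    return ConfirmationResult(qtl_call, "not_confirmed")


def extra_qtl_screen(effect_calls: Sequence[EffectCall], qtl_calls: Sequence[QTLCall],
                     nils: Sequence[NILDefinition]) -> list[tuple[str, str]]:
    """Significant NIL effects not explained by any mapped QTL for the trait.

    A direct NIL-vs-background comparison can reveal loci the genome scan
    missed; an effect is unexplained when none of the NIL's introgressions
    intersects any QTL interval called for that trait.
    """
    by_id = {nil.nil_id: nil for nil in nils}
    out = []
    for eff in effect_calls:
        if not eff.significant:
            continue
        nil = by_id.get(eff.nil_id)
        if nil is None:
            raise ValueError(f"effect call references unknown NIL {eff.nil_id!r}")
        explained = False
        for call in qtl_calls:
            if call.trait is not None and eff.trait != call.trait:
                continue
            for iv in nil.on_chromosome(call.chrom):
                if max(iv[0], call.start) <= min(iv[1], call.end):
                    explained = True
        if not explained:
            out.append((eff.nil_id, eff.trait))
    return out
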