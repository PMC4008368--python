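"""Additive rule-based scoring of evidence bundles, one card per category.

Every order-level category is scored independently by summing the
increments of its fired decision rules; the raw score is normalized to a
0-100 confidence by the category's maximum attainable score (negative raw
scores clamp to 0).  The LTR ruleset is additionally available as a
hand-coded scorer (:func:`score_ltr`); the generic, configuration-driven
evaluator must reproduce it exactly under the shipped default rules, which
the test suite asserts on fuzzed bundles.

The filter agents that recognize non-TE repeats (SSR stretches, rDNA,
host genes) live here too.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import ConfigError
from .evidence import ProfileHit, RuleSet, SimilarityHit
from .features import FeatureSet
from .model import CategoryLabel, Order, TAXONOMY, TEConsensus

# roles whose co-occurrence with a detected terminal repeat supports an LTR call
LTR_TR_ROLES = ("INT", "GAG", "RT", "RH", "AP")
# roles counted when found in the same frame in the same ORF
LTR_COFRAME_ROLES = ("ENV", "AP", "RT", "RH", "GAG")


@dataclass
class EvidenceBundle:
    """All filtered evidence for one consensus; the sole input to scoring."""

    consensus: TEConsensus
    features: FeatureSet
    te_hits: list[SimilarityHit] = field(default_factory=list)
    profile_hits: list[ProfileHit] = field(default_factory=list)
    rdna_hits: list[SimilarityHit] = field(default_factory=list)
    hostgene_hits: list[SimilarityHit] = field(default_factory=list)
    helitron_end_hits: list[SimilarityHit] = field(default_factory=list)

    @property
    def profile_roles(self) -> set[str]:
        return {h.domain_role for h in self.profile_hits}

    def has_terminal_repeat(self, kind: str) -> bool:
        if kind == "any":
            return bool(self.features.terminal_repeats)
        if kind == "none":
            return not self.features.terminal_repeats
        return any(t.kind == kind for t in self.features.terminal_repeats)

    def coframed_roles(self) -> set[str]:
        """Roles that share a (frame, ORF) group with at least one other role."""
        groups: dict[tuple[int, int], set[str]] = {}
        for h in self.profile_hits:
            if h.orf_index is None:
                continue
            groups.setdefault((h.frame, h.orf_index), set()).add(h.domain_role)
        out: set[str] = set()
        for roles in groups.values():
            if len(roles) >= 2:
                out |= roles
        return out

    def has_ssr_tail(self, slack: int = 20) -> bool:
        n = self.features.length
        return any(a.end >= n - slack for a in self.features.ssrs)


@dataclass
class ScoreCard:
    """One category's additive score, confidence and fired-rule trace."""

    category: CategoryLabel
    raw: float
    max_raw: float
    trace: list[tuple[str, float]] = field(default_factory=list)

    @property
    def confidence(self) -> int:
        if self.max_raw <= 0:
            return 0
        value = 100.0 * max(self.raw, 0.0) / self.max_raw
        return min(100, max(0, int(value + 0.5)))


# ---------------------------------------------------------------------------
# generic condition evaluator
# ---------------------------------------------------------------------------

def _in_window(value: float, bounds: dict) -> bool:
    lo = bounds.get("min")
    hi = bounds.get("max")
    return (lo is None or value >= lo) and (hi is None or value <= hi)


def evaluate_condition(cond: dict, bundle: EvidenceBundle, *, tail_slack: int = 20) -> bool:
    """Evaluate one rule condition against a bundle."""
    key, value = next(iter(cond.items()))
    if key == "all":
        return all(evaluate_condition(c, bundle, tail_slack=tail_slack) for c in value)
    if key == "any":
        return any(evaluate_condition(c, bundle, tail_slack=tail_slack) for c in value)
    if key == "not":
        return not evaluate_condition(value, bundle, tail_slack=tail_slack)
    if key == "profile_role":
        return value in bundle.profile_roles
    if key == "no_profile_hits":
        return (not bundle.profile_hits) == bool(value)
    if key == "coframed_role":
        return value in bundle.coframed_roles()
    if key == "terminal_repeat":
        return bundle.has_terminal_repeat(value)
    if key == "blast_hit":
        bank = value.get("bank", "TE_bank")
        pools = {
            "TE_bank": bundle.te_hits,
            "rDNA_bank": bundle.rdna_hits,
            "hostgene_bank": bundle.hostgene_hits,
            "helitron_end_bank": bundle.helitron_end_hits,
        }
        for hit in pools.get(bank, []):
            if "program" in value and hit.program != value["program"]:
                continue
            if "order" in value and hit.subject_category.order != Order(value["order"]):
                continue
            if "te_class" in value and (
                hit.subject_category.te_class is None
                or hit.subject_category.te_class.value != value["te_class"]
            ):
                continue
            if "min_coverage" in value and hit.subject_coverage < value["min_coverage"]:
                continue
            return True
        return False
    if key == "polya":
        return (bundle.features.polya is not None) == bool(value)
    if key == "ssr_tail":
        return bundle.has_ssr_tail(tail_slack) == bool(value)
    if key == "ssr_coverage":
        return _in_window(bundle.features.total_ssr_coverage, value)
    if key == "orf_count":
        min_orf = value.get("min_length", 300)
        count = sum(1 for o in bundle.features.orfs if o.length >= min_orf)
        return _in_window(count, value)
    if key == "length":
        return _in_window(bundle.features.length, value)
    if key == "internal_length":
        return _in_window(bundle.features.internal_length, value)
    if key == "helitron_end":
        for hit in bundle.helitron_end_hits:
            name = hit.subject_id.upper()
            if value == "any":
                return True
            if value == "5prime" and "5END" in name:
                return True
            if value == "3prime" and "3END" in name:
                return True
        return False
    raise ConfigError(f"unknown rule condition keyword {key!r}")


def score_category(bundle: EvidenceBundle, order: Order | str, ruleset: RuleSet) -> ScoreCard:
    """Score one category of the taxonomy by its configured additive rules."""
    order = Order(order)
    spec = ruleset.categories.get(order.value)
    if spec is None:
        raise ConfigError(f"no rules configured for category {order.value}")
    tail_slack = int(ruleset.arbiter.get("tail_slack", 20))
    raw = 0.0
    trace: list[tuple[str, float]] = []
    for rule in spec.rules:
        if evaluate_condition(rule.when, bundle, tail_slack=tail_slack):
            raw += rule.add
            trace.append((rule.name, rule.add))
    return ScoreCard(TAXONOMY[order], raw, spec.max_raw, trace)


def score_all(bundle: EvidenceBundle, ruleset: RuleSet) -> list[ScoreCard]:
    """One ScoreCard per configured TE category, in taxonomy order."""
    return [score_category(bundle, Order(name), ruleset) for name in ruleset.categories]


# ---------------------------------------------------------------------------
# the LTR scorer, hand-coded from the published rules
# ---------------------------------------------------------------------------

def score_ltr(bundle: EvidenceBundle, max_raw: float = 17.0) -> ScoreCard:
    """Score the LTR retrotransposon hypothesis with the published rules.

    +2 for an ENV profile (sufficient on its own); +1 for each of
    INT/GAG/RT/RH/AP present together with a detected terminal direct
    repeat; +1 for each of ENV/AP/RT/RH/GAG found in the same frame in the
    same ORF; +2 per blast program (blastx, tblastx) matching a known LTR
    retrotransposon; +1 when the length without the terminal repeats is
    4000-15000 bp, -1 when it is below 1000 bp or above 15000 bp.
    """
    raw = 0.0
    trace: list[tuple[str, float]] = []
    roles = bundle.profile_roles
    if "ENV" in roles:
        raw += 2
        trace.append(("env_profile_sufficient", 2))
    has_ltr = bundle.has_terminal_repeat("direct")
    for role in LTR_TR_ROLES:
        if role in roles and has_ltr:
            raw += 1
            trace.append((f"{role.lower()}_with_terminal_repeat", 1))
    coframed = bundle.coframed_roles()
    for role in LTR_COFRAME_ROLES:
        if role in coframed:
            raw += 1
            trace.append((f"{role.lower()}_coframed_in_orf", 1))
    for program in ("blastx", "tblastx"):
        if any(h.program == program and h.subject_category.order == Order.LTR
               for h in bundle.te_hits):
            raw += 2
            trace.append((f"{program}_ltr_match", 2))
    internal = bundle.features.internal_length
    if 4000 <= internal <= 15000:
        raw += 1
        trace.append(("internal_length_typical", 1))
    elif internal < 1000 or internal > 15000:
        raw -= 1
        trace.append(("internal_length_atypical", -1))
    return ScoreCard(TAXONOMY[Order.LTR], raw, max_raw, trace)


# ---------------------------------------------------------------------------
# filter agents: SSR / rDNA / host gene
# ---------------------------------------------------------------------------

@dataclass
class FilterResult:
    """Verdict (or sub-threshold annotation) from one non-TE filter agent."""

    category: CategoryLabel
    fired: bool
    coverage: float
    note: str


def apply_filters(bundle: EvidenceBundle, ruleset: RuleSet) -> list[FilterResult]:
    """Decide whether a consensus is an SSR stretch, rDNA or a host gene.

    Verdicts fire only on strong coverage with no competing TE evidence;
    weaker matches are reported as annotations so they reach the evidence
    summary without overriding a TE classification.
    """
    th = ruleset.thresholds
    ssr_min = float(th.get("ssr_filter_min", 75))
    rdna_min = float(th.get("rdna_min", 80))
    hostgene_min = float(th.get("hostgene_min", 75))
    results: list[FilterResult] = []

    has_te_evidence = bool(bundle.te_hits or bundle.profile_hits)
    cov = bundle.features.total_ssr_coverage
    if cov > 0:
        fired = cov >= ssr_min and not has_te_evidence
        results.append(FilterResult(
            TAXONOMY[Order.SSR], fired, cov, f"SSRs {cov:.1f}%"))

    if bundle.rdna_hits:
        best = max(bundle.rdna_hits, key=lambda h: h.subject_coverage)
        fired = best.subject_coverage >= rdna_min
        results.append(FilterResult(
            TAXONOMY[Order.RDNA], fired, best.subject_coverage,
            f"rDNA: {best.subject_id} {best.subject_coverage:.2f}%"))

    if bundle.hostgene_hits:
        best = max(bundle.hostgene_hits, key=lambda h: h.subject_coverage)
        best_te = max((h.subject_coverage for h in bundle.te_hits), default=0.0)
        dominates = best.subject_coverage > best_te and not bundle.profile_hits
        fired = best.subject_coverage >= hostgene_min and dominates
        results.append(FilterResult(
            TAXONOMY[Order.HOST_GENE], fired, best.subject_coverage,
            f"HostGene: {best.subject_id} {best.subject_coverage:.2f}%"))

    return results
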