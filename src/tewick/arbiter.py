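"""Conflict resolution and the end-to-end classification pipeline.

The arbiter compares the normalized score cards of all categories, lets a
non-TE filter verdict win outright, declares a consensus "potential
chimeric" when at least two classifications remain plausible (choosing the
best when its lead is decisive, otherwise emitting the pipe-joined
candidate list), falls back to a class-level call when no order survives
but the positive evidence agrees on a class, assesses completeness, infers
orientation and assembles the output records.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .errors import InputError
from .evidence import (
    ProfileHit,
    RuleSet,
    SimilarityHit,
    detector_params,
    load_rules,
    parse_blast_tabular,
    parse_domtbl,
    read_fasta,
    write_output,
)
from .features import FeatureSet, compute_features, parse_trf_dat
from .model import (
    CategoryLabel,
    ClassificationRecord,
    Order,
    Status,
    TAXONOMY,
    TEClass,
    TEConsensus,
)
from .scoring import EvidenceBundle, FilterResult, ScoreCard, apply_filters, score_all

log = logging.getLogger("tewick")


@dataclass
class ArbiterSettings:
    chimera_conf_min: float = 50.0
    decision_margin: float = 10.0
    completeness_blast_cov: float = 30.0
    completeness_profile_cov: float = 75.0
    tail_slack: int = 20
    length_windows: dict = field(default_factory=dict)

    @classmethod
    def from_ruleset(cls, ruleset: RuleSet) -> "ArbiterSettings":
        a = ruleset.arbiter
        comp = a.get("completeness") or {}
        return cls(
            chimera_conf_min=float(a.get("chimera_conf_min", 50)),
            decision_margin=float(a.get("decision_margin", 10)),
            completeness_blast_cov=float(comp.get("blast_cov", 30)),
            completeness_profile_cov=float(comp.get("profile_cov", 75)),
            tail_slack=int(a.get("tail_slack", 20)),
            length_windows={k: tuple(v) for k, v in (a.get("length_windows") or {}).items()},
        )


@dataclass
class Resolution:
    status: Status
    candidates: list[CategoryLabel]     # best-first; >1 only for undecided chimeras
    te_class: str                       # "I" | "II" | "nonTE" | "Unknown" | pipe-joined
    confidence: int
    note: str = ""

    @property
    def order_text(self) -> str:
        return "|".join(c.order.value for c in self.candidates) if self.candidates else Order.UNKNOWN.value

    @property
    def best_order(self) -> Order:
        return self.candidates[0].order if self.candidates else Order.UNKNOWN


def resolve(
    cards: list[ScoreCard],
    verdicts: list[FilterResult],
    settings: Optional[ArbiterSettings] = None,
) -> Resolution:
    """Pick the final classification from score cards and filter verdicts.

    A fired filter verdict wins outright (non-TE record, status OK).
    Otherwise the cards at or above ``chimera_conf_min`` compete: a single
    survivor is reported as-is; several survivors make the element potential
    chimeric, decided in favour of the top card when its lead is at least
    ``decision_margin``, left as a pipe-joined candidate list otherwise.
    With no survivor the element stays at order Unknown, falling back to a
    class-level call when all positive evidence agrees on one class.
    """
    s = settings or ArbiterSettings()
    fired = [v for v in verdicts if v.fired]
    if fired:
        best = max(fired, key=lambda v: v.coverage)
        conf = min(100, max(0, int(best.coverage + 0.5)))
        return Resolution(Status.OK, [best.category], TEClass.NON_TE.value, conf, best.note)

    survivors = sorted(
        (c for c in cards if c.confidence >= s.chimera_conf_min),
        key=lambda c: (-c.confidence, c.category.order.value),
    )
    if not survivors:
        positive = [c for c in cards if c.raw > 0]
        classes = {c.category.te_class for c in positive}
        if len(classes) == 1:
            conf = max(c.confidence for c in positive)
            te_class = next(iter(classes)).value
            return Resolution(Status.OK, [], te_class, conf,
                              "class-level call: order-level evidence insufficient")
        return Resolution(Status.OK, [], Order.UNKNOWN.value, 0, "no decisive evidence")
    if len(survivors) == 1:
        best = survivors[0]
        return Resolution(Status.OK, [best.category],
                          best.category.te_class.value, best.confidence)
    top, runner = survivors[0], survivors[1]
    if top.confidence - runner.confidence >= s.decision_margin:
        return Resolution(Status.POTENTIAL_CHIMERIC, [top.category],
                          top.category.te_class.value, top.confidence,
                          f"best of {len(survivors)} plausible classifications")
    labels = [c.category for c in survivors]
    classes: list[str] = []
    for c in survivors:
        value = c.category.te_class.value
        if value not in classes:
            classes.append(value)
    return Resolution(Status.POTENTIAL_CHIMERIC, labels, "|".join(classes),
                      top.confidence, "no decision possible between candidates")


# ---------------------------------------------------------------------------
# completeness / orientation
# ---------------------------------------------------------------------------

_EXPECTED_TERMINI: dict[Order, str] = {
    Order.LTR: "direct",
    Order.LARD: "direct",
    Order.TRIM: "direct",
    Order.DIRS: "direct",
    Order.TIR: "inverted",
    Order.MITE: "inverted",
    Order.LINE: "tail",
    Order.SINE: "tail",
}


def assess_completeness(order: Order, bundle: EvidenceBundle,
                        settings: Optional[ArbiterSettings] = None) -> str:
    """Judge whether a classified consensus looks full-length.

    Complete iff (best TE-bank subject coverage strictly exceeds 30% OR best
    profile coverage strictly exceeds 75%) AND the order's expected termini
    are present (direct repeats for LTR/LARD/TRIM/DIRS, inverted repeats for
    TIR/MITE, a polyA or SSR tail for LINE/SINE) AND the length lies in the
    order's expected window.
    """
    s = settings or ArbiterSettings()
    if order not in TAXONOMY or TAXONOMY[order].te_class is None:
        return "incomplete"
    best_blast = max((h.subject_coverage for h in bundle.te_hits), default=0.0)
    best_profile = max((h.profile_coverage for h in bundle.profile_hits), default=0.0)
    if not (best_blast > s.completeness_blast_cov or best_profile > s.completeness_profile_cov):
        return "incomplete"
    expected = _EXPECTED_TERMINI.get(order)
    if expected == "tail":
        if bundle.features.polya is None and not bundle.has_ssr_tail(s.tail_slack):
            return "incomplete"
    elif expected is not None:
        if not bundle.has_terminal_repeat(expected):
            return "incomplete"
    window = s.length_windows.get(order.value)
    if window is not None:
        lo, hi = window
        if not (lo <= bundle.features.length <= hi):
            return "incomplete"
    return "complete"


def orient(bundle: EvidenceBundle) -> str:
    """Coverage-weighted majority strand over retained blast and profile hits.

    Returns "." when there is no stranded evidence or the vote ties.
    """
    plus = minus = 0.0
    for h in bundle.te_hits + bundle.rdna_hits + bundle.hostgene_hits + bundle.helitron_end_hits:
        if h.strand > 0:
            plus += h.subject_coverage
        else:
            minus += h.subject_coverage
    for p in bundle.profile_hits:
        if p.frame > 0:
            plus += p.profile_coverage
        else:
            minus += p.profile_coverage
    if plus > minus:
        return "+"
    if minus > plus:
        return "-"
    return "."


# ---------------------------------------------------------------------------
# bundle assembly
# ---------------------------------------------------------------------------

def link_profiles_to_orfs(hits: list[ProfileHit], features: FeatureSet) -> None:
    """Attach each profile hit to the ORF containing it (same frame), if any.

    The amino-acid alignment span on the translated frame is mapped to
    nucleotide coordinates on the forward strand and matched against the
    detected ORFs.
    """
    n = features.length
    for h in hits:
        k = abs(h.frame)
        nt_from = (h.ali_from - 1) * 3 + k
        nt_to = h.ali_to * 3 + k - 1
        if h.frame < 0:
            nt_from, nt_to = n - nt_to + 1, n - nt_from + 1
        h.orf_index = None
        for idx, orf in enumerate(features.orfs):
            if orf.frame == h.frame and orf.start <= nt_from and nt_to <= orf.end:
                h.orf_index = idx
                break


@dataclass
class EvidenceStore:
    """In-memory evidence store keyed by consensus id (replaces an external DB)."""

    te_hits: dict[str, list[SimilarityHit]] = field(default_factory=dict)
    profile_hits: dict[str, list[ProfileHit]] = field(default_factory=dict)
    rdna_hits: dict[str, list[SimilarityHit]] = field(default_factory=dict)
    hostgene_hits: dict[str, list[SimilarityHit]] = field(default_factory=dict)
    helitron_end_hits: dict[str, list[SimilarityHit]] = field(default_factory=dict)
    ssr_override: dict[str, list] = field(default_factory=dict)

    def add_similarity(self, hits: list[SimilarityHit]) -> None:
        pools = {
            "TE_bank": self.te_hits,
            "rDNA_bank": self.rdna_hits,
            "hostgene_bank": self.hostgene_hits,
            "helitron_end_bank": self.helitron_end_hits,
        }
        for h in hits:
            pools[h.bank].setdefault(h.query_id, []).append(h)

    def add_profiles(self, hits: list[ProfileHit]) -> None:
        for h in hits:
            self.profile_hits.setdefault(h.query_id, []).append(h)


def build_bundle(consensus: TEConsensus, store: EvidenceStore,
                 ruleset: RuleSet) -> EvidenceBundle:
    params = detector_params(ruleset)
    override = store.ssr_override.get(consensus.id)
    features = compute_features(consensus.sequence, params, ssr_override=override)
    profiles = list(store.profile_hits.get(consensus.id, []))
    link_profiles_to_orfs(profiles, features)
    return EvidenceBundle(
        consensus=consensus,
        features=features,
        te_hits=list(store.te_hits.get(consensus.id, [])),
        profile_hits=profiles,
        rdna_hits=list(store.rdna_hits.get(consensus.id, [])),
        hostgene_hits=list(store.hostgene_hits.get(consensus.id, [])),
        helitron_end_hits=list(store.helitron_end_hits.get(consensus.id, [])),
    )


# ---------------------------------------------------------------------------
# evidence summary
# ---------------------------------------------------------------------------

def summarize_evidence(bundle: EvidenceBundle, resolution: Resolution,
                       filters: list[FilterResult]) -> list[str]:
    """Human-readable evidence blocks: coding(...), struct(...), other(...)."""
    coding: list[str] = []
    for program, tag in (("tblastx", "TE_BLRtx"), ("blastx", "TE_BLRx")):
        hits = sorted((h for h in bundle.te_hits if h.program == program),
                      key=lambda h: -h.subject_coverage)
        for h in hits:
            coding.append(f"{tag}: {h.subject_id} {h.subject_coverage:.2f}%")
    for p in sorted(bundle.profile_hits, key=lambda p: (-p.profile_coverage, p.profile_name)):
        coding.append(f"profiles: {p.profile_name} ({p.domain_role}) {p.profile_coverage:.2f}%")

    struct: list[str] = []
    internal = bundle.features.internal_length
    if 4000 <= internal <= 15000:
        struct.append(">4000bps")
    for t in bundle.features.terminal_repeats:
        kind = "TermLTR" if t.kind == "direct" else "TermTIR"
        struct.append(f"{kind}: {t.repeat_length}bp {t.identity:.1f}%")
    n_orfs = len(bundle.features.orfs)
    if n_orfs:
        longest = max(o.length for o in bundle.features.orfs)
        struct.append(f"ORFs: {n_orfs} (longest {longest}bp)")
    if bundle.features.polya is not None:
        struct.append(f"polyA: {bundle.features.polya.length}bp")

    other: list[str] = []
    for f in filters:
        if not f.fired:
            other.append(f.note)
    if resolution.note:
        other.append(resolution.note)

    blocks: list[str] = []
    if coding:
        blocks.append("coding(" + "; ".join(coding) + ")")
    if struct:
        blocks.append("struct(" + "; ".join(struct) + ")")
    if other:
        blocks.append("other(" + "; ".join(other) + ")")
    return blocks


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def classify_bundle(bundle: EvidenceBundle, ruleset: RuleSet,
                    settings: Optional[ArbiterSettings] = None) -> ClassificationRecord:
    """Filters -> scores -> resolve -> completeness -> record, for one bundle."""
    s = settings or ArbiterSettings.from_ruleset(ruleset)
    filters = apply_filters(bundle, ruleset)
    cards = score_all(bundle, ruleset)
    for card in cards:
        for name, inc in card.trace:
            log.debug("%s: %s rule %s fired (%+g)", bundle.consensus.id,
                      card.category.order.value, name, inc)
    resolution = resolve(cards, filters, s)
    if resolution.candidates and resolution.candidates[0].te_class is not None \
            and resolution.candidates[0].order not in (Order.SSR, Order.RDNA, Order.HOST_GENE):
        completeness = assess_completeness(resolution.best_order, bundle, s)
    else:
        completeness = "incomplete"
    return ClassificationRecord(
        te_id=bundle.consensus.id,
        length=bundle.consensus.length,
        orientation=orient(bundle),
        status=resolution.status,
        te_class=resolution.te_class,
        order=resolution.order_text,
        completeness=completeness,
        confidence=resolution.confidence,
        evidence_summary=summarize_evidence(bundle, resolution, filters),
    )


def run_pipeline(
    fasta,
    blastx=None,
    tblastx=None,
    domtbl=None,
    blastn_rdna=None,
    blastn_hostgene=None,
    blastn_helitron=None,
    trf=None,
    config=None,
    out=None,
    subject_lengths: Optional[dict[str, int]] = None,
    permissive: bool = False,
) -> list[ClassificationRecord]:
    """Classify every consensus in a FASTA file from pre-computed evidence.

    All evidence arguments are file paths and optional; ``config`` may be a
    path to a rules YAML or a loaded :class:`RuleSet`.  The run is
    deterministic: identical inputs produce byte-identical output tables.
    In permissive mode a consensus whose scoring fails is reported on stderr
    and skipped instead of aborting.
    """
    ruleset = config if isinstance(config, RuleSet) else load_rules(config)
    settings = ArbiterSettings.from_ruleset(ruleset)
    th = ruleset.thresholds
    blast_cov_min = float(th.get("blast_cov_min", 5))
    profile_cov_min = float(th.get("profile_cov_min", 20))

    consensi = read_fasta(fasta)
    store = EvidenceStore()
    for path, bank, program in (
        (blastx, "TE_bank", "blastx"),
        (tblastx, "TE_bank", "tblastx"),
        (blastn_rdna, "rDNA_bank", "blastn"),
        (blastn_hostgene, "hostgene_bank", "blastn"),
        (blastn_helitron, "helitron_end_bank", "blastn"),
    ):
        if path is not None:
            store.add_similarity(parse_blast_tabular(
                path, bank, program, subject_lengths, blast_cov_min))
    if domtbl is not None:
        store.add_profiles(parse_domtbl(domtbl, profile_cov_min, ruleset.profile_roles))
    if trf is not None:
        store.ssr_override = parse_trf_dat(trf)

    records: list[ClassificationRecord] = []
    for consensus in consensi:
        try:
            bundle = build_bundle(consensus, store, ruleset)
            records.append(classify_bundle(bundle, ruleset, settings))
        except InputError:
            raise
        except Exception:
            if not permissive:
                raise
            log.exception("scoring failed for %s; skipped (permissive mode)", consensus.id)
    if out is not None:
        write_output(records, out)
    return records
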