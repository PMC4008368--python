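from __future__ import annotations

import numpy as np
import pytest

from tewick.evidence import ProfileHit, SimilarityHit, load_rules, parse_subject_category
from tewick.features import FeatureSet, ORFAnnotation, PolyATail, SSRAnnotation, TerminalRepeat
from tewick.model import Order, TEConsensus
from tewick.scoring import EvidenceBundle


@pytest.fixture(scope="session")
def ruleset():
    return load_rules()


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def make_bundle(
    length: int = 5000,
    *,
    te_id: str = "T1",
    repeats: tuple[str, ...] = (),
    repeat_length: int = 200,
    roles: tuple[str, ...] = (),
    coframed: tuple[str, ...] = (),
    blast: tuple[tuple[str, str], ...] = (),   # (program, subject header)
    polya: bool = False,
    ssr_tail: bool = False,
    ssr_coverage: float = 0.0,
    orfs: tuple[tuple[int, int, int], ...] = (),
    rdna_cov: float | None = None,
    hostgene_cov: float | None = None,
    helitron_ends: tuple[str, ...] = (),
) -> EvidenceBundle:
    """Assemble an evidence bundle directly, bypassing the detectors."""
    consensus = TEConsensus(te_id, "A" * length)
    trs = [TerminalRepeat(k, 1, repeat_length, length - repeat_length + 1, length,
                          repeat_length, 98.0) for k in repeats]
    ssrs = []
    if ssr_tail:
        ssrs.append(SSRAnnotation("CA", 2, length - 30, length - 5, 13.0))
    feats = FeatureSet(
        length=length,
        terminal_repeats=trs,
        ssrs=ssrs,
        total_ssr_coverage=ssr_coverage,
        polya=PolyATail("3prime", 15, 1.0) if polya else None,
        orfs=[ORFAnnotation(f, s, e, e - s + 1) for f, s, e in orfs],
    )
    profile_hits = []
    for i, role in enumerate(roles):
        profile_hits.append(ProfileHit(te_id, f"{role}_prof", role, 2, 200, 90.0,
                                       150.0, 1e-30, 5 + 80 * i, 64 + 80 * i))
    for role in coframed:
        profile_hits.append(ProfileHit(te_id, f"{role}_prof", role, 1, 200, 90.0,
                                       150.0, 1e-30, 10, 69, orf_index=0))
    te_hits = []
    for program, subject in blast:
        te_hits.append(SimilarityHit(te_id, subject, parse_subject_category(subject),
                                     program, "TE_bank", 85.0, 1, 600, 101, 700,
                                     1000, 60.0))
    def _nt_hit(bank, subject, cov):
        span = int(cov * 10)
        return SimilarityHit(te_id, subject, parse_subject_category(subject),
                             "blastn", bank, 90.0, 1, span, 1, span, 1000, cov)
    rdna = [_nt_hit("rDNA_bank", "rDNA_28S#rDNA", rdna_cov)] if rdna_cov is not None else []
    hg = [_nt_hit("hostgene_bank", "geneX#Gene", hostgene_cov)] if hostgene_cov is not None else []
    hel = [_nt_hit("helitron_end_bank", f"HelEnd_{e}#RC/Helitron", 90.0)
           for e in helitron_ends]
    return EvidenceBundle(consensus, feats, te_hits=te_hits, profile_hits=profile_hits,
                          rdna_hits=rdna, hostgene_hits=hg, helitron_end_hits=hel)


_ROLES = ("RT", "INT", "GAG", "AP", "RH", "ENV", "EN", "Tase", "YR", "HEL",
          "RPA", "PolB", "ATPase", "other")
_ORDER_HEADERS = ("#LTR/Gypsy", "#DIRS", "#Penelope", "#LINE/L1", "#SINE/tRNA",
                  "#LARD", "#TRIM", "#DNA/hAT", "#MITE", "#Crypton",
                  "#RC/Helitron", "#Maverick", "#nonsense")


def fuzz_bundle(rng: np.random.Generator) -> EvidenceBundle:
    """A random evidence bundle over the full evidence vocabulary."""
    length = int(rng.integers(200, 20000))
    repeats = ()
    if rng.random() < 0.5:
        repeats = tuple(rng.choice(["direct", "inverted"],
                                   size=rng.integers(1, 3), replace=False))
    roles = tuple(rng.choice(_ROLES, size=rng.integers(0, 5), replace=False))
    coframed = ()
    if rng.random() < 0.4:
        coframed = tuple(rng.choice(_ROLES[:8], size=rng.integers(1, 4), replace=False))
    blast = tuple(
        (str(rng.choice(["blastx", "tblastx"])), "S" + str(rng.choice(_ORDER_HEADERS)))
        for _ in range(rng.integers(0, 4))
    )
    orfs = ()
    if rng.random() < 0.5:
        orfs = ((1, 301, 1500),)
    return make_bundle(
        length,
        repeats=repeats,
        repeat_length=min(int(rng.integers(10, 2000)), length // 2 - 1),
        roles=roles,
        coframed=coframed,
        blast=blast,
        polya=bool(rng.random() < 0.3),
        ssr_tail=bool(rng.random() < 0.3),
        ssr_coverage=float(rng.uniform(0, 40)),
        orfs=orfs,
        helitron_ends=("5end", "3end") if rng.random() < 0.15 else (),
    )
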