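"""Seeded generation of synthetic TE consensi with matching evidence files.

Every category of the taxonomy can be emulated without any external data:
a sequence with the category's structural hallmarks is generated (terminal
direct/inverted repeats, polyA tails, SSR stretches, long stop-free ORFs),
and syntactically valid BLAST tabular / HMMER3 domain-table evidence is
fabricated to match, using Repbase-style ``name#Order/Superfamily`` subject
headers so that header parsing is exercised end to end.

The generator records a :class:`PlantedTruth` manifest per element which is
sufficient to predict the rules that fire for the planted category under
the default ruleset, making full-pipeline recovery testable.  Everything is
deterministic under the seed, with byte-stable output files.

These sequences are statistical stand-ins (uniform i.i.d. background, no
real domain coding), not realistic TE models.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .features import (
    DetectorParams,
    find_orfs,
    find_terminal_repeats,
    revcomp,
)
from .model import Order, TAXONOMY, TEConsensus

BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_NON_STOP_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                    if a + b + c not in _STOPS]

#: Repbase-style subject-header suffixes used for the fabricated TE bank.
BANK_HEADERS: dict[Order, str] = {
    Order.LTR: "#LTR/Gypsy",
    Order.DIRS: "#DIRS/Ngaro",
    Order.PLE: "#Penelope",
    Order.LINE: "#LINE/L1",
    Order.SINE: "#SINE/tRNA",
    Order.LARD: "#LARD",
    Order.TRIM: "#TRIM",
    Order.TIR: "#DNA/hAT",
    Order.MITE: "#MITE/Tourist",
    Order.CRYPTON: "#Crypton",
    Order.HELITRON: "#RC/Helitron",
    Order.MAVERICK: "#Maverick",
}

#: Profile names, one per domain role, chosen to exercise role inference.
PROFILE_NAMES: dict[str, str] = {
    "ENV": "ENV_1", "RT": "RVT_1", "INT": "rve_1", "GAG": "GAG_1",
    "AP": "Prot_AP", "RH": "RNaseH_1", "EN": "Endo_EN", "Tase": "Tase_DDE",
    "YR": "YR_1", "HEL": "HEL_hel", "RPA": "RPA_1", "PolB": "PolB_1",
    "ATPase": "ATPase_1",
}


@dataclass
class PlantedTruth:
    """What was planted for one element: features and fabricated evidence."""

    te_id: str
    category: Order
    features: dict = field(default_factory=dict)
    evidence: list[dict] = field(default_factory=list)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def _random_orf_codons(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_NON_STOP_CODONS), size=n_codons)
    return "".join(_NON_STOP_CODONS[i] for i in idx)


def _mutate(rng: np.random.Generator, seq: str, mu: float) -> str:
    if mu <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < mu)[0]
    for i in hits:
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def _plant_orf(rng: np.random.Generator, seq: str, orf_len: int, region_start: int) -> tuple[str, int, int]:
    """Overwrite part of ``seq`` with a stop-free frame +1 ORF ending in TAA.

    Returns (sequence, orf_start, orf_end) with 1-based inclusive coordinates
    of the span the ORF detector will report (bounded by planted stops, the
    trailing stop included).
    """
    # first frame +1 codon boundary at or after region_start, leaving room
    # for the bounding upstream stop
    start0 = region_start
    start0 += (-start0) % 3            # 0-based, multiple of 3 -> frame +1
    n_codons = orf_len // 3
    body = _random_orf_codons(rng, n_codons - 1) + "TAA"
    chars = list(seq)
    chars[start0 - 3:start0] = "TAA"   # upstream bounding stop
    chars[start0:start0 + orf_len] = body
    return "".join(chars), start0 + 1, start0 + orf_len


# ---------------------------------------------------------------------------
# evidence fabrication helpers
# ---------------------------------------------------------------------------

def _blast_record(te_id: str, subject: str, bank: str, program: str, *,
                  slen: int = 1000, s_start: int = 101, s_end: int = 700,
                  q_start: int = 1, q_end: int = 600, pident: float = 85.0,
                  retained: bool = True) -> dict:
    coverage = 100.0 * (abs(s_end - s_start) + 1) / slen
    return {
        "kind": "blast", "bank": bank, "program": program, "te_id": te_id,
        "subject": subject, "pident": pident, "q_start": q_start,
        "q_end": q_end, "s_start": s_start, "s_end": s_end, "slen": slen,
        "coverage": round(coverage, 4), "retained": retained,
    }


def _profile_record(te_id: str, role: str, *, frame: int = 2, tlen: int = 200,
                    hmm_from: int = 11, hmm_to: int = 190, ali_from: int = 5,
                    ali_to: int = 64, qlen: int = 500, retained: bool = True,
                    name: Optional[str] = None) -> dict:
    coverage = 100.0 * (hmm_to - hmm_from + 1) / tlen
    return {
        "kind": "profile", "te_id": te_id, "profile": name or PROFILE_NAMES[role],
        "role": role, "frame": frame, "tlen": tlen, "hmm_from": hmm_from,
        "hmm_to": hmm_to, "ali_from": ali_from, "ali_to": ali_to,
        "qlen": qlen, "coverage": round(coverage, 4), "retained": retained,
    }


def _te_blast_pair(te_id: str, order: Order) -> list[dict]:
    subject = f"{order.value}_cons1{BANK_HEADERS[order]}"
    return [
        _blast_record(te_id, subject, "TE_bank", "blastx"),
        _blast_record(te_id, subject, "TE_bank", "tblastx"),
    ]


def _coframed_profiles(te_id: str, roles: list[str], orf_start: int, orf_end: int) -> list[dict]:
    """Profile hits placed inside a frame +1 ORF, spaced 70 aa apart."""
    out = []
    aa_start = (orf_start - 1) // 3 + 1      # aa coordinate of the ORF start
    for i, role in enumerate(roles):
        a_from = aa_start + 5 + 70 * i
        a_to = a_from + 59
        out.append(_profile_record(te_id, role, frame=1,
                                   ali_from=a_from, ali_to=a_to,
                                   qlen=(orf_end // 3) + 10))
    return out


# ---------------------------------------------------------------------------
# per-category builders
# ---------------------------------------------------------------------------

def make_element(category: Order | str, seed: int, *, mu: float = 0.0,
                 repeat_length: Optional[int] = None,
                 params: Optional[DetectorParams] = None) -> tuple[TEConsensus, PlantedTruth]:
    """Generate one synthetic consensus plus its planted-truth manifest.

    ``mu`` is a per-site substitution rate applied to the right copy of a
    planted terminal repeat; ``repeat_length`` overrides the category's
    default terminal-repeat length.  Deterministic under ``seed``.
    """
    category = Order(category)
    if category not in TAXONOMY or category == Order.UNKNOWN:
        raise ValueError(f"unknown category {category!r}")
    rng = np.random.default_rng(seed)
    te_id = f"{category.value}_{seed}"
    det = params or DetectorParams()

    for _attempt in range(50):
        result = _build(category, te_id, rng, mu, repeat_length)
        if result is None:
            continue
        consensus, truth = result
        if _constraints_ok(category, consensus, det):
            return consensus, truth
    raise RuntimeError(f"could not satisfy structural constraints for {category.value}")


def _constraints_ok(category: Order, consensus: TEConsensus, det: DetectorParams) -> bool:
    seq = consensus.sequence
    if category in (Order.SINE, Order.MITE):
        # the "no long ORF" rule must fire by construction
        if any(o.length >= det.orf_min_length for o in find_orfs(seq, det.orf_min_length)):
            return False
    if category in (Order.LINE, Order.PLE, Order.CRYPTON, Order.DIRS,
                    Order.HELITRON, Order.SINE):
        # these categories must not present a spurious terminal repeat
        if find_terminal_repeats(seq, det.terminal_repeat):
            return False
    return True


def _build(category: Order, te_id: str, rng: np.random.Generator,
           mu: float, repeat_override: Optional[int]):
    ev: list[dict] = []
    feats: dict = {}

    def with_tr(kind: str, rep_len: int, interior: str) -> str:
        rep = _random_dna(rng, rep_len)
        right = _mutate(rng, rep, mu)
        if kind == "inverted":
            right = revcomp(right)
        feats.update(repeat_kind=kind, repeat_length=rep_len, mu=mu)
        return rep + interior + right

    if category == Order.LTR:
        rep_len = repeat_override or 433
        interior = _random_dna(rng, 4500)
        seq = with_tr("direct", rep_len, interior)
        seq, orf_start, orf_end = _plant_orf(rng, seq, 3000, rep_len + 70)
        feats.update(orf=(orf_start, orf_end), interior_length=4500)
        ev += _coframed_profiles(te_id, ["ENV", "AP", "RT", "RH", "GAG", "INT"],
                                 orf_start, orf_end)
        ev += _te_blast_pair(te_id, Order.LTR)
        # sub-threshold host-gene match, reported as an annotation only
        ev.append(_blast_record(te_id, "At1g01010#Gene", "hostgene_bank", "blastn",
                                slen=2000, s_start=1, s_end=331, pident=92.0,
                                retained=True))
    elif category == Order.DIRS:
        seq = _random_dna(rng, 5000)
        for role, frame in (("YR", 1), ("RT", 2), ("RH", 3)):
            ev.append(_profile_record(te_id, role, frame=frame))
        ev += _te_blast_pair(te_id, Order.DIRS)
    elif category == Order.PLE:
        seq = _random_dna(rng, 4000)
        for role, frame in (("EN", 1), ("RT", 2)):
            ev.append(_profile_record(te_id, role, frame=frame))
        ev += _te_blast_pair(te_id, Order.PLE)
    elif category == Order.LINE:
        seq = _random_dna(rng, 4980) + "A" * 20
        feats.update(polya_length=20)
        for role, frame in (("RT", 1), ("EN", 2)):
            ev.append(_profile_record(te_id, role, frame=frame))
        ev += _te_blast_pair(te_id, Order.LINE)
    elif category == Order.SINE:
        seq = _random_dna(rng, 380) + "A" * 20
        feats.update(polya_length=20)
        ev += _te_blast_pair(te_id, Order.SINE)
    elif category == Order.TIR:
        rep_len = repeat_override or 50
        seq = with_tr("inverted", rep_len, _random_dna(rng, 3000 - 2 * rep_len))
        ev.append(_profile_record(te_id, "Tase"))
        ev += _te_blast_pair(te_id, Order.TIR)
    elif category == Order.MITE:
        rep_len = repeat_override or 40
        seq = with_tr("inverted", rep_len, _random_dna(rng, 350 - 2 * rep_len))
        ev += _te_blast_pair(te_id, Order.MITE)
    elif category == Order.CRYPTON:
        seq = _random_dna(rng, 2500)
        ev.append(_profile_record(te_id, "YR"))
        ev += _te_blast_pair(te_id, Order.CRYPTON)
    elif category == Order.HELITRON:
        seq = _random_dna(rng, 4000)
        for role in ("HEL", "RPA"):
            ev.append(_profile_record(te_id, role))
        ev.append(_blast_record(te_id, "HelEnd1_5end#RC/Helitron",
                                "helitron_end_bank", "blastn",
                                slen=200, s_start=1, s_end=180, q_start=1, q_end=180))
        ev.append(_blast_record(te_id, "HelEnd1_3end#RC/Helitron",
                                "helitron_end_bank", "blastn",
                                slen=200, s_start=1, s_end=180,
                                q_start=3821, q_end=4000))
        ev += _te_blast_pair(te_id, Order.HELITRON)
    elif category == Order.MAVERICK:
        seq = _random_dna(rng, 10000)
        for role, frame in (("PolB", 1), ("INT", 2), ("ATPase", 3)):
            ev.append(_profile_record(te_id, role, frame=frame))
        ev += _te_blast_pair(te_id, Order.MAVERICK)
    elif category == Order.LARD:
        rep_len = repeat_override or 400
        seq = with_tr("direct", rep_len, _random_dna(rng, 5000))
        ev += _te_blast_pair(te_id, Order.LARD)
    elif category == Order.TRIM:
        rep_len = repeat_override or 250
        seq = with_tr("direct", rep_len, _random_dna(rng, 1000))
        ev += _te_blast_pair(te_id, Order.TRIM)
    elif category == Order.SSR:
        motif = ["GA", "CT", "TA"][int(rng.integers(0, 3))]
        seq = motif * 250
        feats.update(motif=motif)
    elif category == Order.RDNA:
        seq = _random_dna(rng, 2000)
        ev.append(_blast_record(te_id, "rDNA_28S#rDNA", "rDNA_bank", "blastn",
                                slen=3000, s_start=1, s_end=2850,
                                q_start=1, q_end=1900, pident=96.0))
    elif category == Order.HOST_GENE:
        seq = _random_dna(rng, 1500)
        ev.append(_blast_record(te_id, "At2g02020#Gene", "hostgene_bank", "blastn",
                                slen=1600, s_start=1, s_end=1360,
                                q_start=1, q_end=1350, pident=94.0))
    else:  # pragma: no cover
        raise ValueError(f"unknown category {category!r}")

    feats.setdefault("length", len(seq))
    truth = PlantedTruth(te_id=te_id, category=category, features=feats, evidence=ev)
    return TEConsensus(te_id, seq), truth


# ---------------------------------------------------------------------------
# evidence-file serialization
# ---------------------------------------------------------------------------

def _blast_line(rec: dict) -> str:
    span = abs(rec["s_end"] - rec["s_start"]) + 1
    return "\t".join(str(x) for x in (
        rec["te_id"], rec["subject"], f'{rec["pident"]:.2f}', span, 3, 0,
        rec["q_start"], rec["q_end"], rec["s_start"], rec["s_end"],
        "1e-50", "200.0", rec["slen"],
    ))


def _domtbl_line(rec: dict) -> str:
    frame = rec["frame"]
    query = f'{rec["te_id"]}_fr{frame:+d}'
    fields = [
        rec["profile"], "-", rec["tlen"], query, "-", rec["qlen"],
        "1e-40", "150.0", "0.1", "1", "1", "1e-40", "1e-40", "150.0", "0.1",
        rec["hmm_from"], rec["hmm_to"], rec["ali_from"], rec["ali_to"],
        rec["ali_from"], rec["ali_to"], "0.95", "synthetic",
    ]
    return " ".join(str(x) for x in fields)


def make_evidence(truths: list[PlantedTruth] | PlantedTruth, out_dir,
                  dialect: str = "rich") -> dict[str, Path]:
    """Serialize fabricated evidence to BLAST tabular / domtblout files.

    ``dialect="boundary"`` additionally plants hits sitting exactly on the
    intake thresholds (5% blast subject coverage, 20% profile coverage),
    which the parsers must drop.  Returns the paths keyed by evidence kind.
    """
    if isinstance(truths, PlantedTruth):
        truths = [truths]
    if dialect not in ("rich", "boundary"):
        raise ValueError(f"unknown dialect {dialect!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    streams: dict[str, list[str]] = {
        "blastx": [], "tblastx": [], "domtbl": [],
        "blastn_rdna": [], "blastn_hostgene": [], "blastn_helitron": [],
    }
    key_of = {
        ("TE_bank", "blastx"): "blastx",
        ("TE_bank", "tblastx"): "tblastx",
        ("rDNA_bank", "blastn"): "blastn_rdna",
        ("hostgene_bank", "blastn"): "blastn_hostgene",
        ("helitron_end_bank", "blastn"): "blastn_helitron",
    }
    for truth in truths:
        records = list(truth.evidence)
        if dialect == "boundary":
            records.append(_blast_record(
                truth.te_id, "Boundary_cons#LTR/Copia", "TE_bank", "blastx",
                slen=1000, s_start=1, s_end=50, retained=False))
            records.append(_profile_record(
                truth.te_id, "RT", tlen=250, hmm_from=1, hmm_to=50, retained=False))
        for rec in records:
            if rec["kind"] == "blast":
                streams[key_of[(rec["bank"], rec["program"])]].append(_blast_line(rec))
            else:
                streams["domtbl"].append(_domtbl_line(rec))
    names = {
        "blastx": "te_blastx.tsv", "tblastx": "te_tblastx.tsv",
        "domtbl": "profiles.domtbl",
        "blastn_rdna": "rdna_blastn.tsv", "blastn_hostgene": "hostgene_blastn.tsv",
        "blastn_helitron": "helitron_end_blastn.tsv",
    }
    paths: dict[str, Path] = {}
    for key, lines in streams.items():
        path = out_dir / names[key]
        with open(path, "w", newline="\n") as fh:
            for line in lines:
                fh.write(line + "\n")
        paths[key] = path
    return paths


def write_fasta(consensi: list[TEConsensus], path) -> None:
    with open(path, "w", newline="\n") as fh:
        for c in consensi:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.sequence), 60):
                fh.write(c.sequence[i:i + 60] + "\n")


def write_truth_manifest(truths: list[PlantedTruth], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("#te_id\tcategory\tfeatures\tn_evidence\n")
        for t in truths:
            feats = ",".join(f"{k}={v}" for k, v in sorted(t.features.items(), key=lambda kv: kv[0]))
            fh.write(f"{t.te_id}\t{t.category.value}\t{feats}\t{len(t.evidence)}\n")


def make_panel(seed: int, out_dir, include_filters: bool = True,
               dialect: str = "rich") -> tuple[Path, dict[str, Path], list[PlantedTruth]]:
    """One element per category, written as FASTA + evidence + truth manifest.

    The returned paths plug directly into :func:`tewick.arbiter.run_pipeline`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from .model import FILTER_ORDERS, TE_ORDERS

    orders = list(TE_ORDERS) + (list(FILTER_ORDERS) if include_filters else [])
    consensi: list[TEConsensus] = []
    truths: list[PlantedTruth] = []
    for i, order in enumerate(orders):
        consensus, truth = make_element(order, seed + i)
        consensi.append(consensus)
        truths.append(truth)
    fasta = out_dir / "panel.fasta"
    write_fasta(consensi, fasta)
    paths = make_evidence(truths, out_dir, dialect=dialect)
    write_truth_manifest(truths, out_dir / "truth.tsv")
    return fasta, paths, truths
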