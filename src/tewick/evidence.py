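"""Evidence intake and output: sequences, similarity hits, rules, tables.

Readers for the pre-computed evidence the classifier consumes — BLAST
tabular hits (blastx/tblastx against a TE bank, blastn against rDNA /
host-gene / helitron-end banks) and HMMER3 domain-table hits from six-frame
translations — plus the FASTA reader, the decision-rules configuration
loader and the final tab-separated output writer.

The published intake thresholds are applied here as strict inequalities: a
TE-bank blast hit is retained only when its subject coverage exceeds 5%, a
profile hit only when its profile coverage exceeds 20%.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

import yaml
from Bio import SeqIO

from .errors import ConfigError, InputError
from .model import CategoryLabel, ClassificationRecord, Order, TAXONOMY, TEConsensus, UNKNOWN_LABEL

BANKS = ("TE_bank", "rDNA_bank", "hostgene_bank", "helitron_end_bank")
PROGRAMS = ("blastx", "tblastx", "blastn")

PROFILE_ROLES = ("RT", "INT", "GAG", "AP", "RH", "ENV", "EN", "Tase", "YR",
                 "HEL", "RPA", "PolB", "ATPase", "other")


# ---------------------------------------------------------------------------
# hit records
# ---------------------------------------------------------------------------

@dataclass
class SimilarityHit:
    """One retained BLAST tabular hit with its subject-side coverage."""

    query_id: str
    subject_id: str
    subject_category: CategoryLabel
    program: str
    bank: str
    percent_identity: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    subject_length: int
    subject_coverage: float     # percent of the subject spanned

    @property
    def strand(self) -> int:
        """+1/-1 strand of the query relative to the subject."""
        return -1 if (self.q_end < self.q_start) != (self.s_end < self.s_start) else 1


@dataclass
class ProfileHit:
    """One retained HMM-profile domain hit on a six-frame translation."""

    query_id: str               # consensus id (frame suffix stripped)
    profile_name: str
    domain_role: str
    frame: int                  # +1..+3, -1..-3
    profile_length: int
    profile_coverage: float     # percent of the profile columns spanned
    score: float
    e_value: float
    ali_from: int = 0           # aa coordinates on the translated frame
    ali_to: int = 0
    orf_index: Optional[int] = None


# ---------------------------------------------------------------------------
# subject-header category parsing
# ---------------------------------------------------------------------------

# Repbase-style "#Order/Superfamily" aliases, uppercased
_ORDER_ALIASES: dict[str, Order] = {
    "LTR": Order.LTR,
    "DIRS": Order.DIRS,
    "PLE": Order.PLE,
    "PENELOPE": Order.PLE,
    "LINE": Order.LINE,
    "SINE": Order.SINE,
    "LARD": Order.LARD,
    "TRIM": Order.TRIM,
    "TIR": Order.TIR,
    "DNA": Order.TIR,
    "MITE": Order.MITE,
    "CRYPTON": Order.CRYPTON,
    "HELITRON": Order.HELITRON,
    "RC": Order.HELITRON,
    "MAVERICK": Order.MAVERICK,
    "POLINTON": Order.MAVERICK,
    "RDNA": Order.RDNA,
    "SSR": Order.SSR,
    "GENE": Order.HOST_GENE,
    "HOSTGENE": Order.HOST_GENE,
}


def parse_subject_category(subject_id: str, override: Optional[dict[str, str]] = None) -> CategoryLabel:
    """Category of a databank subject from its ``name#Order/Superfamily`` header.

    ``override`` maps exact subject names to order names for banks that do
    not use the header convention.  Unparseable headers map to Unknown.
    """
    if override and subject_id in override:
        key = override[subject_id].upper()
        order = _ORDER_ALIASES.get(key)
        return TAXONOMY[order] if order else UNKNOWN_LABEL
    if "#" not in subject_id:
        return UNKNOWN_LABEL
    tag = subject_id.split("#", 1)[1].split("/", 1)[0].strip().upper()
    order = _ORDER_ALIASES.get(tag)
    return TAXONOMY[order] if order else UNKNOWN_LABEL


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, on_duplicate: str = "error") -> list[TEConsensus]:
    """Read consensus sequences, uppercasing and N-masking ambiguity codes.

    Record order is preserved.  Duplicate identifiers raise (strict mode,
    default) or are uniquified with a numeric suffix
    (``on_duplicate="uniquify"``).
    """
    if on_duplicate not in ("error", "uniquify"):
        raise ConfigError(f"on_duplicate must be 'error' or 'uniquify', got {on_duplicate!r}")
    out: list[TEConsensus] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        seq = "".join(c if c in "ACGTN" else "N" for c in seq)
        name = rec.id
        if name in seen:
            if on_duplicate == "error":
                raise InputError(f"{path}: duplicate sequence id {name!r}")
            seen[name] += 1
            name = f"{name}.{seen[name]}"
        else:
            seen[name] = 0
        try:
            out.append(TEConsensus(name, seq))
        except ValueError as exc:
            raise InputError(f"{path}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

def parse_blast_tabular(
    path,
    bank: str,
    program: str,
    subject_lengths: Optional[dict[str, int]] = None,
    blast_cov_min: float = 5.0,
    category_override: Optional[dict[str, str]] = None,
) -> list[SimilarityHit]:
    """Parse a 12/13-column BLAST tabular file and apply the intake filter.

    The 13th column, when present, is the subject length (``outfmt '6 std
    slen'``); otherwise every subject must appear in ``subject_lengths``.
    TE-bank hits are retained only when subject coverage strictly exceeds
    ``blast_cov_min`` (default 5%); hits against the other banks are all
    kept, since their filter agents reason about sub-threshold matches too.
    """
    if bank not in BANKS:
        raise ConfigError(f"unknown bank {bank!r}; expected one of {BANKS}")
    if program not in PROGRAMS:
        raise ConfigError(f"unknown blast program {program!r}")
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 12:
                raise InputError(f"{path}:{lineno}: expected >=12 tab-separated columns")
            qid, sid = fields[0], fields[1]
            try:
                pident = float(fields[2])
                q_start, q_end = int(fields[6]), int(fields[7])
                s_start, s_end = int(fields[8]), int(fields[9])
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: malformed numeric field: {exc}") from exc
            if len(fields) >= 13:
                slen = int(fields[12])
            elif subject_lengths and sid in subject_lengths:
                slen = subject_lengths[sid]
            else:
                raise InputError(
                    f"{path}:{lineno}: no subject length for {sid!r}; "
                    "supply a 13-column table (slen) or a subject-length index"
                )
            if slen <= 0:
                raise InputError(f"{path}:{lineno}: non-positive subject length for {sid!r}")
            coverage = 100.0 * (abs(s_end - s_start) + 1) / slen
            if bank == "TE_bank" and coverage <= blast_cov_min:
                continue
            hits.append(
                SimilarityHit(
                    query_id=qid,
                    subject_id=sid,
                    subject_category=parse_subject_category(sid, category_override),
                    program=program,
                    bank=bank,
                    percent_identity=pident,
                    q_start=q_start,
                    q_end=q_end,
                    s_start=s_start,
                    s_end=s_end,
                    subject_length=slen,
                    subject_coverage=round(coverage, 4),
                )
            )
    return hits


# ---------------------------------------------------------------------------
# HMMER3 domain table
# ---------------------------------------------------------------------------

_DEFAULT_ROLE_PATTERNS: list[tuple[str, str]] = [
    ("ENV", "ENV"), ("RVT", "RT"), ("RNASE", "RH"), ("RVE", "INT"),
    ("INTEG", "INT"), ("ATPASE", "ATPase"), ("TASE", "Tase"),
    ("TRANSPOS", "Tase"), ("DDE", "Tase"), ("INT", "INT"), ("GAG", "GAG"),
    ("PROT", "AP"), ("PEPSIN", "AP"), ("POLB", "PolB"), ("DNAPOL", "PolB"),
    ("RPA", "RPA"), ("HEL", "HEL"), ("RECOMB", "YR"), ("YR", "YR"),
    ("ENDO", "EN"), ("EN", "EN"), ("RH", "RH"), ("AP", "AP"),
]


def infer_domain_role(profile_name: str, patterns: Optional[list[tuple[str, str]]] = None) -> str:
    """First-match substring inference of a profile's protein-domain role."""
    upper = profile_name.upper()
    for pat, role in (patterns or _DEFAULT_ROLE_PATTERNS):
        if pat.upper() in upper:
            return role
    return "other"


def _split_frame_suffix(query_name: str) -> tuple[str, int]:
    if "_fr" not in query_name:
        raise InputError(f"query name {query_name!r} lacks a _fr frame suffix")
    base, _, suffix = query_name.rpartition("_fr")
    try:
        frame = int(suffix)
    except ValueError as exc:
        raise InputError(f"malformed frame suffix in {query_name!r}") from exc
    if frame not in (1, 2, 3, -1, -2, -3):
        raise InputError(f"frame {frame} out of range in {query_name!r}")
    return base, frame


def parse_domtbl(
    path,
    profile_cov_min: float = 20.0,
    role_patterns: Optional[list[tuple[str, str]]] = None,
) -> list[ProfileHit]:
    """Parse a HMMER3 ``--domtblout`` table of profile hits.

    The query names are six-frame translations carrying ``_fr{+1..-3}``
    suffixes; the profile is the target.  Profile coverage is the spanned
    fraction of the profile columns; hits are retained only when it strictly
    exceeds ``profile_cov_min`` (default 20%).
    """
    hits: list[ProfileHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 22:
                raise InputError(f"{path}:{lineno}: expected >=22 whitespace-separated columns")
            profile = fields[0]
            try:
                tlen = int(fields[2])
                i_evalue = float(fields[12])
                dom_score = float(fields[13])
                hmm_from, hmm_to = int(fields[15]), int(fields[16])
                ali_from, ali_to = int(fields[17]), int(fields[18])
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: malformed numeric field: {exc}") from exc
            query_id, frame = _split_frame_suffix(fields[3])
            if tlen <= 0:
                raise InputError(f"{path}:{lineno}: non-positive profile length")
            coverage = 100.0 * (hmm_to - hmm_from + 1) / tlen
            if coverage <= profile_cov_min:
                continue
            hits.append(
                ProfileHit(
                    query_id=query_id,
                    profile_name=profile,
                    domain_role=infer_domain_role(profile, role_patterns),
                    frame=frame,
                    profile_length=tlen,
                    profile_coverage=round(coverage, 4),
                    score=dom_score,
                    e_value=i_evalue,
                    ali_from=ali_from,
                    ali_to=ali_to,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# decision rules
# ---------------------------------------------------------------------------

CONDITION_KEYWORDS = frozenset({
    "all", "any", "not",
    "profile_role", "no_profile_hits", "coframed_role",
    "terminal_repeat", "blast_hit", "polya", "ssr_tail", "ssr_coverage",
    "orf_count", "length", "internal_length", "helitron_end",
})

_TR_VALUES = ("direct", "inverted", "any", "none")


@dataclass
class Rule:
    name: str
    add: float
    when: dict


@dataclass
class CategoryRules:
    order: str
    max_raw: float
    rules: list[Rule]


@dataclass
class RuleSet:
    """The full decision-rules configuration (thresholds + per-category rules)."""

    thresholds: dict
    detectors: dict
    arbiter: dict
    profile_roles: list[tuple[str, str]]
    categories: dict[str, CategoryRules]
    raw: dict = field(default_factory=dict)   # merged YAML, for round-tripping

    def to_dict(self) -> dict:
        return copy.deepcopy(self.raw)


def _validate_condition(cond, where: str) -> None:
    if not isinstance(cond, dict) or len(cond) != 1:
        raise ConfigError(f"{where}: condition must be a single-key mapping, got {cond!r}")
    key, value = next(iter(cond.items()))
    if key not in CONDITION_KEYWORDS:
        raise ConfigError(f"{where}: unknown rule condition keyword {key!r}")
    if key in ("all", "any"):
        if not isinstance(value, list) or not value:
            raise ConfigError(f"{where}: {key} needs a non-empty list")
        for sub in value:
            _validate_condition(sub, where)
    elif key == "not":
        _validate_condition(value, where)
    elif key == "terminal_repeat":
        if value not in _TR_VALUES:
            raise ConfigError(f"{where}: terminal_repeat must be one of {_TR_VALUES}")
    elif key == "blast_hit":
        if not isinstance(value, dict):
            raise ConfigError(f"{where}: blast_hit needs a mapping")
        unknown = set(value) - {"program", "order", "te_class", "bank", "min_coverage"}
        if unknown:
            raise ConfigError(f"{where}: unknown blast_hit fields {sorted(unknown)}")
    elif key in ("ssr_coverage", "orf_count", "length", "internal_length"):
        if not isinstance(value, dict) or not set(value) <= {"min", "max", "min_length"}:
            raise ConfigError(f"{where}: {key} takes a mapping with min/max bounds")
    elif key == "helitron_end":
        if value not in ("5prime", "3prime", "any"):
            raise ConfigError(f"{where}: helitron_end must be 5prime/3prime/any")


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def default_rules_text() -> str:
    return resources.files("tewick").joinpath("data/decision_rules.yaml").read_text()


def load_rules(path=None) -> RuleSet:
    """Load the decision rules, overlaying a user YAML file on the defaults.

    Validates every rule condition keyword and checks that each category's
    declared ``max_raw`` is at least the maximum attainable raw score (the
    sum of its positive increments); ``max_raw: auto`` adopts that maximum.
    """
    data = yaml.safe_load(default_rules_text())
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        data = _deep_merge(data, user)

    categories: dict[str, CategoryRules] = {}
    for order_name, spec in (data.get("categories") or {}).items():
        try:
            Order(order_name)
        except ValueError:
            raise ConfigError(f"categories.{order_name}: not a known order") from None
        rules = []
        for i, rspec in enumerate(spec.get("rules") or []):
            where = f"categories.{order_name}.rules[{i}]"
            for req in ("name", "add", "when"):
                if req not in rspec:
                    raise ConfigError(f"{where}: missing {req!r}")
            add = rspec["add"]
            if not isinstance(add, (int, float)) or add != add or abs(add) == float("inf"):
                raise ConfigError(f"{where}: increment must be finite")
            _validate_condition(rspec["when"], where)
            rules.append(Rule(str(rspec["name"]), float(add), rspec["when"]))
        attainable = sum(r.add for r in rules if r.add > 0)
        max_raw = spec.get("max_raw", "auto")
        if max_raw == "auto":
            max_raw = attainable
        elif not isinstance(max_raw, (int, float)):
            raise ConfigError(f"categories.{order_name}: max_raw must be a number or 'auto'")
        elif max_raw < attainable:
            raise ConfigError(
                f"categories.{order_name}: max_raw {max_raw} is below the "
                f"attainable raw score {attainable}"
            )
        if max_raw <= 0:
            raise ConfigError(f"categories.{order_name}: max_raw must be positive")
        categories[order_name] = CategoryRules(order_name, float(max_raw), rules)

    roles = [(str(a), str(b)) for a, b in (data.get("profile_roles") or _DEFAULT_ROLE_PATTERNS)]
    return RuleSet(
        thresholds=data.get("thresholds") or {},
        detectors=data.get("detectors") or {},
        arbiter=data.get("arbiter") or {},
        profile_roles=roles,
        categories=categories,
        raw=data,
    )


def dump_rules(ruleset: RuleSet, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(ruleset.to_dict(), fh, sort_keys=True)


def detector_params(ruleset: RuleSet):
    """Build feature-detector parameter objects from a RuleSet."""
    from .features import DetectorParams, PolyAParams, SSRParams, TerminalRepeatParams

    det = ruleset.detectors
    return DetectorParams(
        terminal_repeat=TerminalRepeatParams(**(det.get("terminal_repeat") or {})),
        ssr=SSRParams(**(det.get("ssr") or {})),
        polya=PolyAParams(**(det.get("polya") or {})),
        orf_min_length=int((det.get("orf") or {}).get("min_length", 300)),
    )


# ---------------------------------------------------------------------------
# output table
# ---------------------------------------------------------------------------

OUTPUT_COLUMNS = ("te_id", "length", "orientation", "status", "class",
                  "order", "completeness", "confidence", "evidence")


def format_record(rec: ClassificationRecord) -> str:
    evidence = "; ".join(rec.evidence_summary) if rec.evidence_summary else "."
    return "\t".join([
        rec.te_id,
        str(rec.length),
        rec.orientation,
        rec.status.value,
        rec.te_class,
        rec.order,
        rec.completeness,
        str(int(rec.confidence)),
        evidence,
    ])


def write_output(records: Iterable[ClassificationRecord], path) -> None:
    """Write the final classification table (one tab-separated row per consensus)."""
    with open(path, "w", newline="\n") as fh:
        fh.write("#" + "\t".join(OUTPUT_COLUMNS) + "\n")
        for rec in records:
            fh.write(format_record(rec) + "\n")
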