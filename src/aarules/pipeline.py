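"""End-to-end mining pipeline: FASTA → windows → itemsets → rules → report.

The five stages are (1) read the protein sequence(s), (2) partition into
fixed-length window transactions, (3) mine frequent itemsets with Apriori,
(4) generate and confidence-filter association rules, and (5) score the
strong rules with the interestingness measures and keep the useful ones.
Each FASTA record is processed independently (one protein per run is the
normal case).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

from . import interestingness as im
from . import rules as re_
from .apriori import CountingMode, apriori, write_itemsets_tsv
from .errors import ValidationError
from .interestingness import RuleMetrics
from .rules import AssociationRule
from .sequence_io import DEFAULT_WINDOW_LEN, partition, read_fasta

SCHEMA_VERSION = 1

#: The study's per-protein minimum-support presets (absolute counts), keyed by
#: UniProt accession with protein-name aliases.
PRESETS = {
    "P68871": 3,   # hemoglobin subunit beta, 147 aa
    "P38398": 5,   # BRCA1, 1863 aa
    "P13569": 5,   # CFTR, 1480 aa
    "P30518": 4,   # vasopressin V2 receptor, 371 aa
    "P08100": 4,   # rhodopsin, 348 aa
    "hbb": 3,
    "brca1": 5,
    "cftr": 5,
    "v2r": 4,
    "rhodopsin": 4,
}


@dataclass(frozen=True)
class PipelineConfig:
    fasta_path: str
    window_len: int = DEFAULT_WINDOW_LEN
    minsup_count: int = 3
    min_conf: Fraction = re_.DEFAULT_MIN_CONF
    mode: CountingMode = CountingMode.PAPER
    output_dir: str | None = None
    report_formats: tuple = ("tsv", "json")
    strict: bool = True

    def __post_init__(self):
        if self.minsup_count < 1:
            raise ValidationError(f"minsup_count must be >= 1, got {self.minsup_count}")
        if not (0 < Fraction(self.min_conf) <= 1):
            raise ValidationError(f"min_conf must be in (0, 1], got {self.min_conf}")
        if self.window_len < 1:
            raise ValidationError(f"window_len must be >= 1, got {self.window_len}")
        object.__setattr__(self, "min_conf", Fraction(self.min_conf))
        object.__setattr__(self, "mode", CountingMode.coerce(self.mode))


@dataclass
class SequenceReport:
    """Counts and scored rules for one input sequence."""

    sequence_id: str
    length: int
    n_windows: int
    itemsets_by_size: dict
    total_itemsets: int
    total_rules: int
    strong_rules: int
    rejected_rules: int
    useful_rules: int
    redundant_rules: int
    useful: list = field(default_factory=list)      # (AssociationRule, RuleMetrics)
    redundant: list = field(default_factory=list)

    def check_conservation(self) -> None:
        assert self.useful_rules + self.redundant_rules == self.strong_rules
        assert self.strong_rules + self.rejected_rules == self.total_rules


@dataclass
class MiningReport:
    """Full pipeline output: per-sequence reports plus the run configuration."""

    config: PipelineConfig
    sequences: list = field(default_factory=list)

    def sequence(self, sequence_id: str) -> SequenceReport:
        for s in self.sequences:
            if s.sequence_id == sequence_id:
                return s
        raise KeyError(sequence_id)


def _json_metric(value):
    if value is im.UNDEFINED:
        return None
    if value == math.inf:
        return "inf"
    return round(float(value), 6)


def _rule_entry(rule: AssociationRule, metrics: RuleMetrics | None = None) -> dict:
    entry = {
        "antecedent": "".join(rule.antecedent),
        "consequent": "".join(rule.consequent),
        "confidence": f"{rule.confidence.numerator}/{rule.confidence.denominator}",
        "confidence_pct": re_.confidence_pct(rule.confidence),
    }
    if metrics is not None:
        entry.update(
            lift=_json_metric(metrics.lift),
            improve=_json_metric(metrics.improve),
            bi_lift=_json_metric(metrics.bi_lift),
            bi_improve=_json_metric(metrics.bi_improve),
            bi_confidence=_json_metric(metrics.bi_confidence),
            verdict=metrics.verdict,
        )
    return entry


def mine_sequence(seq, config: PipelineConfig) -> tuple:
    """Run stages 2–5 on one sequence; returns (SequenceReport, artifacts).

    ``artifacts`` carries the intermediate objects (db, itemset table, scored
    rule lists) for callers that want more than the counts.
    """
    db = partition(seq, config.window_len)
    table = apriori(db, config.minsup_count, config.mode)
    candidates = re_.enumerate_rules(table)
    scored = re_.score_confidences(candidates, db, config.mode)
    accepted, rejected = re_.filter_strong(scored, config.min_conf)
    measured = im.score_rules(accepted, db, config.mode)
    useful = [(r, m) for r, m in measured if m.verdict == im.USEFUL]
    redundant = [(r, m) for r, m in measured if m.verdict == im.REDUNDANT]
    report = SequenceReport(
        sequence_id=seq.id,
        length=seq.length,
        n_windows=db.n_windows,
        itemsets_by_size={k: len(v) for k, v in table.by_size.items()},
        total_itemsets=table.total,
        total_rules=len(scored),
        strong_rules=len(accepted),
        rejected_rules=len(rejected),
        useful_rules=len(useful),
        redundant_rules=len(redundant),
        useful=useful,
        redundant=redundant,
    )
    report.check_conservation()
    artifacts = {
        "db": db,
        "table": table,
        "scored": scored,
        "accepted": accepted,
        "rejected": rejected,
        "measured": measured,
    }
    return report, artifacts


def run_pipeline(config: PipelineConfig) -> MiningReport:
    """Run the full pipeline; write TSV/JSON artifacts when output_dir is set."""
    sequences = read_fasta(config.fasta_path, strict=config.strict)
    report = MiningReport(config=config)
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    for seq in sequences:
        seq_report, artifacts = mine_sequence(seq, config)
        report.sequences.append(seq_report)
        if out_dir and "tsv" in config.report_formats:
            prefix = out_dir if len(sequences) == 1 else out_dir / seq.id
            prefix.mkdir(parents=True, exist_ok=True)
            write_itemsets_tsv(artifacts["table"], prefix / "itemsets.tsv")
            re_.write_rules_tsv(
                artifacts["accepted"] + artifacts["rejected"],
                artifacts["db"],
                config.mode,
                prefix / "rules.tsv",
            )
            im.write_metrics_tsv(artifacts["measured"], prefix / "metrics.tsv")
    if out_dir and "json" in config.report_formats:
        write_report_json(report, out_dir / "report.json")
    return report


def report_to_dict(report: MiningReport) -> dict:
    cfg = report.config
    return {
        "schema_version": SCHEMA_VERSION,
        "config": {
            "fasta_path": str(cfg.fasta_path),
            "window_len": cfg.window_len,
            "minsup_count": cfg.minsup_count,
            "min_conf": f"{cfg.min_conf.numerator}/{cfg.min_conf.denominator}",
            "mode": cfg.mode.value,
        },
        "sequences": [
            {
                "id": s.sequence_id,
                "length": s.length,
                "n_windows": s.n_windows,
                "itemsets_by_size": {str(k): v for k, v in s.itemsets_by_size.items()},
                "total_itemsets": s.total_itemsets,
                "total_rules": s.total_rules,
                "strong_rules": s.strong_rules,
                "rejected_rules": s.rejected_rules,
                "useful_rules": s.useful_rules,
                "redundant_rules": s.redundant_rules,
                "useful": [_rule_entry(r, m) for r, m in s.useful],
                "redundant": [_rule_entry(r, m) for r, m in s.redundant],
            }
            for s in report.sequences
        ],
    }


def write_report_json(report: MiningReport, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(report_to_dict(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _rule_keys(pairs) -> set:
    return {("".join(r.antecedent), "".join(r.consequent)) for r, _ in pairs}


def compare_runs(report_a: MiningReport, report_b: MiningReport) -> dict:
    """Diff the strong/useful rule sets of two runs over the same sequences.

    Returns, per sequence id, the rules strong or useful in one run but not
    the other (as ``antecedent -> consequent`` strings).
    """
    ids_a = {s.sequence_id for s in report_a.sequences}
    ids_b = {s.sequence_id for s in report_b.sequences}
    if ids_a != ids_b:
        raise ValidationError(
            f"reports cover different sequences: {sorted(ids_a)} vs {sorted(ids_b)}"
        )
    diff = {}
    for sid in sorted(ids_a):
        a, b = report_a.sequence(sid), report_b.sequence(sid)
        strong_a = _rule_keys(a.useful) | _rule_keys(a.redundant)
        strong_b = _rule_keys(b.useful) | _rule_keys(b.redundant)
        useful_a, useful_b = _rule_keys(a.useful), _rule_keys(b.useful)
        fmt = lambda keys: sorted(f"{x} -> {y}" for x, y in keys)
        diff[sid] = {
            "strong_only_a": fmt(strong_a - strong_b),
            "strong_only_b": fmt(strong_b - strong_a),
            "useful_only_a": fmt(useful_a - useful_b),
            "useful_only_b": fmt(useful_b - useful_a),
        }
    return diff


def config_from_file(path, **overrides) -> PipelineConfig:
    """Build a PipelineConfig from a YAML or JSON file; kwargs override."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"config file {path} must contain a mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)
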