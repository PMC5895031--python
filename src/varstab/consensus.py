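"""Eight-predictor consensus triage of missense variants.

Each variant carries one call from each of eight effect predictors
(PROVEAN, SIFT, PolyPhen-2, PhD-SNP, SNAP2, SNPs&GO, FATHMM, I-Mutant 3).
Calls are binarized to damaging/benign under per-tool rules — categorical
vocabularies for published labels, thresholds for raw scores — and a
variant is labelled deleterious (D) when at least five of the eight tools
call it damaging, otherwise neutral (N).

When a table carries published labels, :func:`classify_table` emits a
concordance report comparing the re-derived labels against the published
ones row by row; published labels are never overwritten.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .catalog import ProteinVariant, parse_protein_token
from .errors import InputError, MappingError, PanelError

TOOLS = (
    "PROVEAN",
    "SIFT",
    "PolyPhen2",
    "PhD-SNP",
    "SNAP2",
    "SNPsGO",
    "FATHMM",
    "IMutant3",
)

DAMAGING = "damaging"
BENIGN = "benign"

#: Votes needed for a deleterious (D) consensus label.
CONSENSUS_THRESHOLD = 5


def _norm(category: str) -> str:
    # collapse case and the "of/in stability" wording variants
    s = " ".join(category.strip().lower().split())
    return s.replace("decrease in stability", "decrease of stability").replace(
        "increase in stability", "increase of stability"
    )


@dataclass(frozen=True)
class ToolRule:
    """Binarization rule for one predictor.

    ``categories`` maps normalized categorical labels to a side; a numeric
    ``threshold``/``direction`` pair handles raw scores ("lt": damaging
    when score < threshold, "gt": damaging when score > threshold).
    I-Mutant uses a three-band DDG rule handled specially.
    """

    categories: Mapping[str, str]
    threshold: float | None = None
    direction: str | None = None

    def binarize(self, tool: str, raw: object) -> str:
        if isinstance(raw, (int, float)) and not isinstance(raw, bool):
            if self.threshold is None:
                raise MappingError(f"{tool}: no numeric rule for score {raw!r}")
            if self.direction == "lt":
                return DAMAGING if raw < self.threshold else BENIGN
            return DAMAGING if raw > self.threshold else BENIGN
        key = _norm(str(raw))
        try:
            return self.categories[key]
        except KeyError:
            raise MappingError(f"{tool}: unrecognized value {raw!r}") from None


class _IMutantRule(ToolRule):
    """DDG bands: < -0.5 destabilizing (damaging); middle band and > +0.5 benign votes."""

    def binarize(self, tool: str, raw: object) -> str:
        if isinstance(raw, (int, float)) and not isinstance(raw, bool):
            return DAMAGING if raw < -0.5 else BENIGN
        return super().binarize(tool, raw)


def default_rules() -> dict[str, ToolRule]:
    """Per-tool binarization rules matching the published thresholds.

    SIFT: score < 0.05 deleterious. SNPs&GO: score > 0.5 disease.
    PolyPhen-2: benign < 0.15, possibly damaging 0.15-0.84 (counted as a
    benign vote), probably damaging >= 0.85. I-Mutant 3: DDG < -0.5
    kcal/mol destabilizing.
    """
    return {
        "PROVEAN": ToolRule({"deleterious": DAMAGING, "neutral": BENIGN}),
        "SIFT": ToolRule(
            {"damaging": DAMAGING, "deleterious": DAMAGING, "tolerated": BENIGN},
            threshold=0.05,
            direction="lt",
        ),
        "PolyPhen2": ToolRule(
            {
                "probably damaging": DAMAGING,
                "possibly damaging": BENIGN,
                "benign": BENIGN,
            },
            threshold=0.85,
            direction="gt",
        ),
        "PhD-SNP": ToolRule({"disease": DAMAGING, "neutral": BENIGN}),
        "SNAP2": ToolRule({"effect": DAMAGING, "non-neutral": DAMAGING, "neutral": BENIGN}),
        "SNPsGO": ToolRule(
            {"disease": DAMAGING, "neutral": BENIGN}, threshold=0.5, direction="gt"
        ),
        "FATHMM": ToolRule({"damaging": DAMAGING, "tolerated": BENIGN}),
        "IMutant3": _IMutantRule(
            {
                "large decrease of stability": DAMAGING,
                "decrease of stability": DAMAGING,
                "neutral": BENIGN,
                "increase of stability": BENIGN,
                "large increase of stability": BENIGN,
            }
        ),
    }


def binarize_call(
    tool: str, raw: object, rules: Mapping[str, ToolRule] | None = None
) -> str:
    """Map one raw predictor output to damaging/benign."""
    rules = rules or default_rules()
    if tool not in rules:
        raise MappingError(f"no binarization rule for tool {tool!r}")
    return rules[tool].binarize(tool, raw)


@dataclass
class ConsensusResult:
    """Vote count and N/D label for one variant."""

    variant_id: str
    mutation: str
    calls: dict[str, str]
    votes: int
    label: str
    printed_label: str | None = None

    @property
    def protein_variant(self) -> ProteinVariant:
        return parse_protein_token(self.mutation, source_id=self.variant_id)


def consensus_classify(calls: Mapping[str, str]) -> tuple[int, str]:
    """Count damaging votes over the eight tools; >= 5 gives label D."""
    if set(calls) != set(TOOLS):
        missing = set(TOOLS) - set(calls)
        extra = set(calls) - set(TOOLS)
        raise PanelError(
            f"panel must contain exactly one call per tool "
            f"(missing {sorted(missing)}, unexpected {sorted(extra)})"
        )
    bad = {t: c for t, c in calls.items() if c not in (DAMAGING, BENIGN)}
    if bad:
        raise PanelError(f"non-binary calls: {bad}")
    votes = sum(1 for c in calls.values() if c == DAMAGING)
    return votes, ("D" if votes >= CONSENSUS_THRESHOLD else "N")


@dataclass
class ConcordanceReport:
    """Row-by-row agreement between re-derived and published labels."""

    n_rows: int
    n_with_printed: int
    n_match: int
    mismatches: list[dict] = field(default_factory=list)

    @property
    def printed_d_count(self) -> int | None:
        return self._printed_d

    def __post_init__(self) -> None:
        self._printed_d = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "rows": self.n_rows,
                "rows_with_printed_label": self.n_with_printed,
                "matches": self.n_match,
                "mismatches": self.mismatches,
            },
            indent=2,
        )


def load_predictor_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV predictor table (id, mutation, eight tool columns,
    optional printed_label)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("id", "mutation", *TOOLS) if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    if df.empty:
        raise InputError(f"{path}: no data rows")
    return df


def load_table1() -> pd.DataFrame:
    """The packaged 52-row TSPO missense predictor panel with published labels."""
    ref = resources.files("varstab.data").joinpath("table1_tspo.tsv")
    with resources.as_file(ref) as path:
        return load_predictor_table(path)


def classify_table(
    table: pd.DataFrame,
    rules: Mapping[str, ToolRule] | None = None,
) -> tuple[list[ConsensusResult], ConcordanceReport]:
    """Classify every row of a predictor table and audit published labels.

    Numeric-looking cells are binarized through the tool's threshold rule,
    everything else through its categorical vocabulary.  Published labels
    (column ``printed_label``) are compared, never replaced.
    """
    if table.empty:
        raise InputError("empty predictor table")
    rules = rules or default_rules()
    results: list[ConsensusResult] = []
    report = ConcordanceReport(n_rows=len(table), n_with_printed=0, n_match=0)
    printed_d = 0
    has_printed = "printed_label" in table.columns
    for _, row in table.iterrows():
        calls = {
            tool: binarize_call(tool, _maybe_number(row[tool]), rules)
            for tool in TOOLS
        }
        votes, label = consensus_classify(calls)
        printed = None
        if has_printed and isinstance(row["printed_label"], str):
            printed = row["printed_label"].strip() or None
        result = ConsensusResult(
            variant_id=str(row["id"]),
            mutation=str(row["mutation"]),
            calls=calls,
            votes=votes,
            label=label,
            printed_label=printed,
        )
        results.append(result)
        if printed:
            report.n_with_printed += 1
            if printed == "D":
                printed_d += 1
            if printed == label:
                report.n_match += 1
            else:
                report.mismatches.append(
                    {
                        "id": result.variant_id,
                        "mutation": result.mutation,
                        "derived": label,
                        "votes": votes,
                        "printed": printed,
                    }
                )
    report._printed_d = printed_d if has_printed else None
    return results, report


def _maybe_number(value: object) -> object:
    if isinstance(value, str):
        try:
            return float(value)
        except ValueError:
            return value
    return value


def results_to_frame(results: Sequence[ConsensusResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"id": r.variant_id, "mutation": r.mutation, "votes": r.votes, "label": r.label}
        if r.printed_label is not None:
            row["printed_label"] = r.printed_label
        row.update(r.calls)
        rows.append(row)
    return pd.DataFrame(rows)


def region_enrichment(
    results: Iterable[ConsensusResult],
    ranges: Sequence[tuple[int, int]],
    use_printed: bool = False,
) -> dict:
    """Count deleterious variants inside residue ranges (union semantics).

    A variant falling in several overlapping ranges is counted once in the
    total.  ``use_printed`` counts the published D set instead of the
    re-derived one.
    """
    for start, end in ranges:
        if start > end:
            raise InputError(f"inverted residue interval ({start}, {end})")
    d_set = [
        r
        for r in results
        if (r.printed_label if use_printed else r.label) == "D"
    ]
    per_range: list[dict] = []
    union_ids: set[str] = set()
    for start, end in ranges:
        members = [
            r.mutation for r in d_set if start <= r.protein_variant.position <= end
        ]
        per_range.append(
            {"start": start, "end": end, "count": len(members), "mutations": members}
        )
        union_ids.update(members)
    return {
        "ranges": per_range,
        "total_in_union": len(union_ids),
        "total_deleterious": len(d_set),
    }


def conservation_overlay(
    results: Iterable[ConsensusResult],
    track: Sequence[int],
    min_score: int = 8,
) -> dict:
    """Deleterious variants at residues with conservation score >= min_score.

    ``track`` is a per-residue conservation grade from 1 (variable) to
    9 (conserved); its length must cover every variant position.
    """
    if not 1 <= min_score <= 9:
        raise InputError(f"min_score {min_score} outside [1, 9]")
    bad = [s for s in track if not 1 <= s <= 9]
    if bad:
        raise InputError(f"conservation scores outside [1, 9]: {bad[:5]}")
    d_set = [r for r in results if r.label == "D"]
    subset = []
    for r in d_set:
        pos = r.protein_variant.position
        if pos > len(track):
            raise InputError(
                f"variant {r.mutation} at residue {pos} beyond track length {len(track)}"
            )
        if track[pos - 1] >= min_score:
            subset.append(r)
    return {
        "min_score": min_score,
        "conserved_deleterious": [r.mutation for r in subset],
        "count": len(subset),
        "total_deleterious": len(d_set),
    }
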