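"""Candidate-gene levels from three evidence categories, plus a prime mark.

A transcript can carry up to three independent lines of evidence for a role
in the water-deficit stress response:

* it is unique to a stress-treated cDNA library,
* it is differentially expressed under stress (microarray / RT-PCR),
* it colocalizes with a stress-related QTL confidence interval.

The candidate *level* is simply how many categories hold: one -> Level I,
two -> Level II, all three -> Level III; zero -> no level (kept for audit).
A prime mark (``I′``, ``II′``, ...) flags stress-related gene ontology and is
independent of the level itself.  The final short-listing of candidates is a
judgement call in practice, so instead of hard-coding one rule the module
exposes a small filter expression language over the evidence fields, e.g.
``level >= I and (prime or differentially_expressed)``.
"""

from __future__ import annotations

import ast
import csv
import io
from dataclasses import dataclass

import pandas as pd

PRIME = "′"

LEVEL_NAMES = {0: "none", 1: "I", 2: "II", 3: "III"}

TABLE4_COLUMNS = ["part", "id", "sts_marker", "chromosome", "position_cM",
                  "qtl", "expression", "putative_function", "category"]


@dataclass(frozen=True)
class EvidenceProfile:
    """Resolved evidence flags for one transcript.

    Detail fields (expression direction/tissue, region id) are carried only
    when the corresponding flag is set.
    """

    transcript_id: str
    in_stress_library_unique: bool
    differentially_expressed: bool
    qtl_colocalized: bool
    stress_go: bool
    expression_detail: str = ""
    region_detail: str = ""

    def __post_init__(self) -> None:
        if self.expression_detail and not self.differentially_expressed:
            raise ValueError("expression detail without the DE flag")
        if self.region_detail and not self.qtl_colocalized:
            raise ValueError("region detail without the colocalization flag")


@dataclass(frozen=True)
class CandidateRecord:
    transcript_id: str
    level: str          # none / I / II / III
    prime: bool
    categories: frozenset

    @property
    def category_label(self) -> str:
        if self.level == "none":
            return ""
        return self.level + (PRIME if self.prime else "")


def classify(profiles) -> list[CandidateRecord]:
    """Map evidence profiles to candidate records.

    The level is the count of satisfied categories (symmetric in the three),
    and the prime mark mirrors the stress-ontology flag exactly.
    """
    records = []
    for prof in profiles:
        cats = frozenset(
            name for name, flag in (
                ("stress_library", prof.in_stress_library_unique),
                ("differential_expression", prof.differentially_expressed),
                ("qtl_colocalized", prof.qtl_colocalized),
            ) if flag
        )
        records.append(CandidateRecord(
            transcript_id=prof.transcript_id,
            level=LEVEL_NAMES[len(cats)],
            prime=prof.stress_go,
            categories=cats,
        ))
    return records


_ALLOWED_NODES = (
    ast.Expression, ast.BoolOp, ast.UnaryOp, ast.Compare, ast.Name, ast.Load,
    ast.And, ast.Or, ast.Not, ast.Eq, ast.NotEq, ast.Lt, ast.LtE, ast.Gt,
    ast.GtE, ast.Constant,
)

_FILTER_NAMES = {"none": 0, "I": 1, "II": 2, "III": 3, "true": True, "false": False}
_FILTER_FIELDS = ("level", "prime", "in_stress_library_unique",
                  "differentially_expressed", "qtl_colocalized", "stress_go")


def _compile_filter(expression: str):
    tree = ast.parse(expression, mode="eval")
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_NODES):
            raise ValueError(f"unsupported syntax in filter: {ast.dump(node)[:40]}")
        if isinstance(node, ast.Name) and node.id not in (*_FILTER_NAMES, *_FILTER_FIELDS):
            raise ValueError(f"unknown name in filter: {node.id}")
    code = compile(tree, "<candidate-filter>", "eval")

    def run(env: dict) -> bool:
        return bool(eval(code, {"__builtins__": {}}, {**_FILTER_NAMES, **env}))

    return run


def filter_candidates(records: list[CandidateRecord],
                      profiles_by_id: dict[str, EvidenceProfile],
                      expression: str) -> list[CandidateRecord]:
    """Select candidate records with a boolean filter expression.

    Available names: ``level`` (ordered none < I < II < III), ``prime``,
    and the three raw evidence flags plus ``stress_go``.
    """
    run = _compile_filter(expression)
    level_rank = {name: rank for rank, name in LEVEL_NAMES.items()}
    out = []
    for rec in records:
        prof = profiles_by_id[rec.transcript_id]
        env = {
            "level": level_rank[rec.level],
            "prime": rec.prime,
            "in_stress_library_unique": prof.in_stress_library_unique,
            "differentially_expressed": prof.differentially_expressed,
            "qtl_colocalized": prof.qtl_colocalized,
            "stress_go": prof.stress_go,
        }
        if run(env):
            out.append(rec)
    return out


def render_expression(labels: list[tuple[str, str]]) -> str:
    """Render (direction, tissue) pairs as arrow notation: ``↑ leaf, ↓ root``."""
    arrows = {"induced": "↑", "repressed": "↓"}
    parts = []
    for direction, tissue in labels:
        if direction == "reciprocal":
            parts.append(f"↑↓ {tissue}")
        else:
            parts.append(f"{arrows[direction]} {tissue}")
    return ", ".join(parts)


def candidate_table(records: list[CandidateRecord], hits: pd.DataFrame,
                    regions: pd.DataFrame, annotations: pd.DataFrame,
                    expression: pd.DataFrame) -> pd.DataFrame:
    """Report rows for levelled candidates: one row per (candidate, locus).

    Columns follow the candidate-report layout (id, STS marker, chromosome,
    position, region traits, expression arrows, putative function, category),
    sorted by chromosome, position, id.  Unanchored candidates (no locus)
    get one row with empty locus fields.  Dangling transcript ids in the
    annotation/expression joins raise a consistency error naming them.
    """
    ann = annotations.set_index("tc_id") if not annotations.empty else None
    expr_by_id: dict[str, list[tuple[str, str]]] = {}
    if not expression.empty:
        for row in expression.itertuples(index=False):
            expr_by_id.setdefault(row.transcript_id, []).append((row.direction, row.tissue))
    hit_by_id: dict[str, list] = {}
    if not hits.empty:
        for row in hits.itertuples(index=False):
            hit_by_id.setdefault(row.tc_id, []).append(row)
    rows = []
    for rec in records:
        if rec.level == "none":
            continue
        func = ""
        if ann is not None and rec.transcript_id in ann.index:
            func = str(ann.at[rec.transcript_id, "function_label"])
        expr_text = render_expression(expr_by_id.get(rec.transcript_id, []))
        loci = hit_by_id.get(rec.transcript_id, [None])
        for locus in loci:
            if locus is None:
                rows.append((rec.transcript_id, "", "", "", "", expr_text,
                             func, rec.category_label))
                continue
            traits = ""
            sub = regions[(regions["chromosome"] == locus.chromosome)
                          & (regions["lo_cM"] <= locus.position_cM)
                          & (locus.position_cM <= regions["hi_cM"])]
            if not sub.empty:
                traits = str(sub.iloc[0]["traits"])
            rows.append((rec.transcript_id, locus.marker_id, locus.chromosome,
                         locus.position_cM, traits, expr_text, func,
                         rec.category_label))
    out = pd.DataFrame(rows, columns=["id", "sts_marker", "chromosome",
                                      "position_cM", "qtl", "expression",
                                      "putative_function", "category"])
    return out.sort_values(
        ["chromosome", "position_cM", "id"],
        key=lambda s: s.map(lambda v: (v == "", v)), kind="mergesort",
    ).reset_index(drop=True)


def load_candidate_fixture(path) -> pd.DataFrame:
    """Read a candidate report TSV preserving every cell verbatim as text."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        rows = list(reader)
    if header != TABLE4_COLUMNS:
        raise ValueError(f"unexpected candidate table header: {header}")
    return pd.DataFrame(rows, columns=header)


def dump_candidate_fixture(df: pd.DataFrame) -> str:
    """Serialise a candidate report back to TSV text (inverse of the loader)."""
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(list(df.columns))
    for row in df.itertuples(index=False):
        writer.writerow(list(row))
    return buf.getvalue()


def regional_candidate_counts(candidates: pd.DataFrame, regions: pd.DataFrame
                              ) -> dict[int, int]:
    """Candidate rows per chromosome whose locus falls in a QTL region there.

    Rows without a mapped position (empty chromosome) are skipped.  Counts
    are of report rows, i.e. one per candidate entry.
    """
    counts: dict[int, int] = {}
    for row in candidates.itertuples(index=False):
        chrom_text = str(row.chromosome).strip()
        if not chrom_text:
            continue
        chrom = int(chrom_text)
        pos = float(row.position_cM)
        sub = regions[(regions["chromosome"].astype(int) == chrom)
                      & (regions["lo_cM"].astype(float) <= pos)
                      & (pos <= regions["hi_cM"].astype(float))]
        if not sub.empty:
            counts[chrom] = counts.get(chrom, 0) + 1
    return counts


__all__ = ["EvidenceProfile", "CandidateRecord", "classify",
           "filter_candidates", "candidate_table", "render_expression",
           "load_candidate_fixture", "dump_candidate_fixture",
           "regional_candidate_counts", "PRIME", "TABLE4_COLUMNS"]
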