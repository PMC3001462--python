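"""Recurrent cancer-mutation overlay onto pattern positions.

Parses a COSMIC-style mutation table (tab-separated, or compact amino-acid
change strings like ``"L861Q(26)"``), joins the mutated positions with the
selected pattern positions and region annotations, and quantifies the
overlap with a one-sided Fisher exact test over a stated reference range of
positions.  The enrichment test is an extension beyond a plain table join
and is labelled as such in the report metadata.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import fisher_exact

from .contrast import ContrastResults
from .structure import TetherAnnotation


class MutationParseError(ValueError):
    """Malformed mutation record, naming the offending row."""


@dataclass(frozen=True)
class MutationRecord:
    """One recurrent somatic mutation in reference (pre-mature) numbering."""

    refpos: int
    wt: str
    variant: str
    primary_site: str
    count: int

    def __post_init__(self) -> None:
        if self.wt == self.variant:
            raise ValueError(f"wt == variant at {self.refpos}")
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")

    @property
    def label(self) -> str:
        return f"{self.wt}{self.refpos}{self.variant}({self.count})"


_COMPACT = re.compile(r"^([A-Z])(\d+)([A-Z])\((\d+)\)$")


def parse_aa_change(text: str, where: str = "") -> MutationRecord:
    """Parse a compact change string like ``'E709K(9)'`` (count in parens)."""
    m = _COMPACT.match(text.strip())
    if not m:
        raise MutationParseError(
            f"malformed amino-acid change {text!r}"
            + (f" at {where}" if where else "")
        )
    wt, pos, var, count = m.group(1), int(m.group(2)), m.group(3), int(m.group(4))
    return MutationRecord(pos, wt, var, "", count)


def read_mutations(path: str | Path) -> list[MutationRecord]:
    """Read a mutation TSV with header (position, wt, variant, site, count).

    The ``position`` column may instead hold compact strings like
    ``"L861Q(26)"`` (then wt/variant/count columns are ignored if absent); a
    cell may hold several space-separated compact strings.  Counts reported
    more than once for the same amino-acid change are summed.
    """
    records: list[MutationRecord] = []
    lines = Path(path).read_text().splitlines()
    body = [
        (ln, line) for ln, line in enumerate(lines, start=1)
        if line.strip() and not line.startswith("#")
    ]
    if not body:
        return []
    start = 0
    first = body[0][1].split("\t")[0].strip().lower()
    if first in {"position", "pos", "mutation"}:
        start = 1
    for ln, line in body[start:]:
        parts = [p.strip() for p in line.split("\t")]
        where = f"{path}:{ln}"
        if _COMPACT.match(parts[0]) or " " in parts[0]:
            site = parts[1] if len(parts) > 1 else ""
            for token in parts[0].split():
                rec = parse_aa_change(token, where)
                records.append(
                    MutationRecord(rec.refpos, rec.wt, rec.variant, site, rec.count)
                )
        elif len(parts) >= 5:
            try:
                records.append(
                    MutationRecord(
                        int(parts[0]), parts[1], parts[2], parts[3], int(parts[4])
                    )
                )
            except ValueError as exc:
                raise MutationParseError(f"{where}: {exc}") from exc
        else:
            raise MutationParseError(
                f"{where}: expected 5 columns or compact change strings, "
                f"got {line!r}"
            )
    return merge_duplicates(records)


def merge_duplicates(records: Iterable[MutationRecord]) -> list[MutationRecord]:
    """Sum counts of identical amino-acid changes (first site kept)."""
    merged: dict[tuple[int, str, str], MutationRecord] = {}
    for r in records:
        key = (r.refpos, r.wt, r.variant)
        if key in merged:
            prev = merged[key]
            site = prev.primary_site or r.primary_site
            merged[key] = MutationRecord(
                r.refpos, r.wt, r.variant, site, prev.count + r.count
            )
        else:
            merged[key] = r
    return list(merged.values())


@dataclass
class OverlayReport:
    """Per-mutation join with pattern positions plus the enrichment test."""

    table: pd.DataFrame
    contingency: tuple[tuple[int, int], tuple[int, int]] | None
    fisher_p: float | None
    odds_ratio: float | None
    reference_range: tuple[int, int]
    excluded_positions: tuple[int, ...]
    metadata: dict

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def overlay(
    muts: Sequence[MutationRecord],
    result: ContrastResults,
    annot: TetherAnnotation | None = None,
    reference_range: tuple[int, int] | None = None,
) -> OverlayReport:
    """Intersect recurrent mutations with the selected pattern positions.

    One row per mutated position: whether it is a selected pattern position,
    its region/tether annotation and total recurrence.  Enrichment is a
    one-sided (greater) Fisher exact test on the 2x2 table of
    mutated-position x pattern-position over all reference positions in
    ``reference_range`` (default: span of the result's reference numbering).
    Positions outside the range are flagged and excluded from the table.
    """
    selected = set(result.selected_refpos)
    all_refpos = [c.refpos for c in result.calls if c.refpos is not None]
    if reference_range is None:
        if not all_refpos:
            raise ValueError(
                "result carries no reference numbering; pass reference_range"
            )
        reference_range = (min(all_refpos), max(all_refpos))
    lo, hi = reference_range
    muts = merge_duplicates(muts)
    by_pos: dict[int, list[MutationRecord]] = {}
    for m in muts:
        by_pos.setdefault(m.refpos, []).append(m)
    rows = []
    excluded = []
    for pos in sorted(by_pos):
        in_range = lo <= pos <= hi
        if not in_range:
            excluded.append(pos)
        region, tether = ("", "none")
        if annot is not None:
            region, tether = annot.regions.get(pos, ("", "none"))
        recs = by_pos[pos]
        rows.append(
            {
                "refpos": pos,
                "mutations": " ".join(r.label for r in sorted(recs, key=lambda r: r.label)),
                "primary_sites": ";".join(
                    sorted({r.primary_site for r in recs if r.primary_site})
                ),
                "total_count": sum(r.count for r in recs),
                "selected": pos in selected,
                "region": region,
                "tether_class": tether,
                "in_range": in_range,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "refpos", "mutations", "primary_sites", "total_count",
            "selected", "region", "tether_class", "in_range",
        ],
    )
    contingency = fisher_p = odds = None
    if by_pos:
        mut_pos = {p for p in by_pos if lo <= p <= hi}
        pat_pos = {p for p in selected if lo <= p <= hi}
        n_range = hi - lo + 1
        a = len(mut_pos & pat_pos)
        b = len(pat_pos - mut_pos)
        c = len(mut_pos - pat_pos)
        d = n_range - a - b - c
        contingency = ((a, b), (c, d))
        odds, fisher_p = fisher_exact([[a, b], [c, d]], alternative="greater")
        odds = float(odds)
        fisher_p = float(fisher_p)
    return OverlayReport(
        table=table,
        contingency=contingency,
        fisher_p=fisher_p,
        odds_ratio=odds,
        reference_range=reference_range,
        excluded_positions=tuple(excluded),
        metadata={
            "enrichment": "one-sided Fisher exact test (extension beyond the "
            "plain table join)",
            "reference_range": list(reference_range),
        },
    )
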