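"""Contrast Hierarchical Alignment (CHA) text rendering.

A CHA shows three layers at once: a small query display alignment, the
foreground family's consensus with weighted residue frequencies, and the
background composition, topped by a score histogram and a dot row marking
the selected pattern positions.  Frequencies are printed in integer tenths:
a '6' under a residue means it occurs in 60-70% of the weighted sequences.
The top band is closed, so a fully conserved residue (100%) also prints '9'
— a single-character display cannot show '10'.
"""

from __future__ import annotations

import html as _html
from dataclasses import dataclass
from typing import Sequence

from .alignment import Alignment, column_profile
from .contrast import ContrastResults

#: Histogram ramp, blank for zero then four quarter bands of (0, 1].
HISTOGRAM_GLYPHS = " .:|#"
DOT = "*"


def freq_digit(freq: float | None) -> str:
    """Integer-tenths digit for a frequency; blank when undefined (all-gap).

    Digit ``d`` covers the band ``[d/10, (d+1)/10)``; the top band is closed,
    so any frequency >= 0.9 — including exactly 1.0 — renders '9'.
    """
    if freq is None:
        return " "
    if not 0.0 <= freq <= 1.0 + 1e-12:
        raise ValueError(f"frequency outside [0, 1]: {freq}")
    return str(min(int(freq * 10), 9))


def _histogram_glyph(height: float) -> str:
    if height <= 0:
        return HISTOGRAM_GLYPHS[0]
    band = min(int(height * 4), 3) if height < 1.0 else 3
    return HISTOGRAM_GLYPHS[1 + band]


@dataclass(frozen=True)
class CHADocument:
    """Rendered CHA: labelled monospaced rows of equal character length."""

    query_ids: tuple[str, ...]
    rows: tuple[tuple[str, str], ...]  # (label, body) pairs
    column_window: tuple[int, int]  # [start, stop) alignment columns
    gutter_width: int

    @property
    def lines(self) -> tuple[str, ...]:
        return tuple(
            f"{label:<{self.gutter_width}}{body}" for label, body in self.rows
        )

    def text(self) -> str:
        return "\n".join(self.lines) + "\n"

    def to_html(self) -> str:
        body = _html.escape(self.text())
        return (
            "<html><body><pre style=\"font-family: monospace\">\n"
            + body
            + "</pre></body></html>\n"
        )


def render_cha(
    aln: Alignment,
    result: ContrastResults,
    query_ids: Sequence[str],
    window: tuple[int, int] | None = None,
) -> CHADocument:
    """Render the contrast as a CHA text block.

    ``window`` is a half-open ``[start, stop)`` range of alignment columns
    (default: all).  Rows: histogram, pattern-dot row, one row per query
    sequence, foreground consensus ('conserved') with total sequence count,
    weighted-frequency digits ('wt_res_freqs') with the effective count, and
    the background consensus/frequency pair.
    """
    for q in query_ids:
        aln.sequence(q)  # raises KeyError for unknown ids
    n_cols = aln.n_columns
    if window is None:
        window = (0, n_cols)
    start, stop = window
    if not (0 <= start < stop <= n_cols):
        raise ValueError(f"window {window} outside columns [0, {n_cols})")
    cols = range(start, stop)

    model = result.model
    part = result.partition
    fore_idx = [aln.index_of(i) for i in part.fore_ids]
    back_idx = [aln.index_of(i) for i in part.back_ids]
    w = model.weights
    fore_prof = column_profile(aln, w, fore_idx)
    back_prof = column_profile(aln, w, back_idx)
    hist = result.histogram

    def consensus_rows(prof, idx):
        letters, digits = [], []
        for c in cols:
            p = prof[c]
            cons = p.consensus
            if cons is None:
                letters.append(GAP_CHAR)
                digits.append(" ")
            else:
                letters.append(cons)
                digits.append(freq_digit(p.freqs[cons]))
        eff = float(w.weights[idx].sum())
        return "".join(letters), "".join(digits), eff, len(idx)

    GAP_CHAR = "-"
    fore_cons, fore_digits, fore_eff, fore_n = consensus_rows(fore_prof, fore_idx)
    back_cons, back_digits, back_eff, back_n = consensus_rows(back_prof, back_idx)

    rows: list[tuple[str, str]] = []
    rows.append(("histogram", "".join(_histogram_glyph(hist[c]) for c in cols)))
    rows.append(
        ("pattern", "".join(DOT if result.calls[c].selected else " " for c in cols))
    )
    for q in query_ids:
        rows.append((q, aln.sequence(q)[start:stop]))
    rows.append((f"conserved ({fore_n})", fore_cons))
    rows.append((f"wt_res_freqs ({fore_eff:.1f})", fore_digits))
    rows.append((f"background ({back_n})", back_cons))
    rows.append((f"bk_res_freqs ({back_eff:.1f})", back_digits))

    gutter = max(len(label) for label, _ in rows) + 2
    return CHADocument(
        query_ids=tuple(query_ids),
        rows=tuple(rows),
        column_window=(start, stop),
        gutter_width=gutter,
    )
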