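"""Comparison reports in the published table layout, dotplots, ledgers.

A :class:`ComparisonReport` interleaves HSP rows and break rows in genome
order — the layout of the published strain-comparison tables: per HSP the
paired positions, truncated two-decimal identity, raw match/total counts
and gap characters; per break either the unaligned interval, "directly
adjacent", or the number of overlapping bases, plus a comment.  An
aggregate row sums the HSP rows.  Output is deterministic byte-for-byte for
fixed input (tsv, json or markdown).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .align import HSP, aggregate_identity
from .breaks import BreakEvent, colinear_chain, tile_and_break

COLUMNS = ["tag", "position_a", "position_b", "identity", "match_total", "gaps", "comment"]


@dataclass
class ComparisonReport:
    query_name: str
    subject_name: str
    hsps: list[HSP]
    breaks: list[BreakEvent]
    tag_prefix: str = "HSP"
    header_info: dict = field(default_factory=dict)  # parameter hash, seed, ...

    @property
    def aggregate(self) -> tuple[int, int, float]:
        return aggregate_identity(self.hsps)


def build_report(
    query_name: str,
    subject_name: str,
    hsps: Sequence[HSP],
    q_len: int,
    s_len: int,
    q_seq: Optional[str] = None,
    tag_prefix: str = "HSP",
    header_info: Optional[dict] = None,
) -> ComparisonReport:
    """Select the colinear chain, tile it, and assemble the report."""
    chain = colinear_chain(hsps)
    if not chain:
        raise ValueError("no plus-strand colinear HSPs to report")
    events = tile_and_break(chain, q_len, s_len, q_seq=q_seq)
    return ComparisonReport(
        query_name=query_name, subject_name=subject_name,
        hsps=chain, breaks=events, tag_prefix=tag_prefix,
        header_info=dict(header_info or {}),
    )


def _interval(iv: Optional[tuple[int, int]]) -> str:
    return f"{iv[0]}-{iv[1]}" if iv else ""


def _break_side(gap: Optional[tuple[int, int]], relation: str, overlap: int) -> str:
    if relation == "gap":
        return _interval(gap)
    if relation == "overlap":
        return f"{overlap} bp overlap"
    return "directly adjacent"


def report_rows(report: ComparisonReport) -> list[dict]:
    """Interleaved HSP/break rows plus a final aggregate row."""
    rows: list[dict] = []
    hsp_serial = 0
    brk_serial = 0
    # tile_and_break emits breaks in order: an optional leading terminal
    # break, one break per inter-HSP junction, an optional trailing one
    hsps = sorted(report.hsps, key=lambda h: (h.q_start, h.s_start))
    breaks = list(report.breaks)
    ordered: list[tuple[str, object]] = []
    bi = 0
    leading = (
        breaks
        and breaks[0].terminal
        and ((breaks[0].q_gap or (0,))[0] == 1 or (breaks[0].s_gap or (0,))[0] == 1)
    )
    if leading:
        ordered.append(("break", breaks[0]))
        bi = 1
    for k, h in enumerate(hsps):
        ordered.append(("hsp", h))
        if k < len(hsps) - 1 and bi < len(breaks):
            ordered.append(("break", breaks[bi]))
            bi += 1
    for ev in breaks[bi:]:
        ordered.append(("break", ev))
    for kind, obj in ordered:
        if kind == "hsp":
            h = obj
            hsp_serial += 1
            rows.append({
                "tag": f"{report.tag_prefix}{hsp_serial}",
                "position_a": f"{h.q_start}-{h.q_end}",
                "position_b": f"{h.s_start}-{h.s_end}",
                "identity": f"{h.identity:.2f}",
                "match_total": f"{h.match_bases}/{h.total_columns}",
                "gaps": str(h.gap_chars),
                "comment": "",
            })
        else:
            ev = obj
            brk_serial += 1
            comment = ev.annotation or _describe(ev)
            rows.append({
                "tag": f"{report.tag_prefix.replace('HSP', '') or ''}break{brk_serial}",
                "position_a": _break_side(ev.q_gap, ev.q_relation, ev.q_overlap),
                "position_b": _break_side(ev.s_gap, ev.s_relation, ev.s_overlap),
                "identity": "",
                "match_total": "",
                "gaps": "",
                "comment": comment,
            })
    total, match, display = report.aggregate
    rows.append({
        "tag": "aggregate",
        "position_a": report.query_name,
        "position_b": report.subject_name,
        "identity": f"{display:.2f}",
        "match_total": f"{match}/{total}",
        "gaps": "",
        "comment": f"{len(report.hsps)} HSPs, {len(report.breaks)} breaks",
    })
    return rows


def _describe(ev: BreakEvent) -> str:
    if ev.category == "insertion_in_q":
        return f"{ev.combined_length} bp insertion in query (primary {ev.primary_length} bp)"
    if ev.category == "insertion_in_s":
        return f"{ev.combined_length} bp insertion in subject (primary {ev.primary_length} bp)"
    if ev.category == "replacement":
        q = (ev.q_gap[1] - ev.q_gap[0] + 1) if ev.q_gap else 0
        s = (ev.s_gap[1] - ev.s_gap[0] + 1) if ev.s_gap else 0
        return f"replacement: {q} bp (query) <-> {s} bp (subject)"
    return "adjacency artifact"


def render_tsv(rows: list[dict], header_info: Optional[dict] = None) -> str:
    lines = []
    for k in sorted(header_info or {}):
        lines.append(f"# {k}: {header_info[k]}")
    lines.append("\t".join(COLUMNS))
    for r in rows:
        lines.append("\t".join(r[c] for c in COLUMNS))
    return "\n".join(lines) + "\n"


def parse_tsv(text: str) -> list[dict]:
    rows = []
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    header = lines[0].split("\t")
    for ln in lines[1:]:
        rows.append(dict(zip(header, ln.split("\t"))))
    return rows


def render_json(rows: list[dict], header_info: Optional[dict] = None) -> str:
    return json.dumps({"header": header_info or {}, "rows": rows}, indent=1,
                      sort_keys=True) + "\n"


def parse_json(text: str) -> list[dict]:
    return json.loads(text)["rows"]


def render_markdown(rows: list[dict], header_info: Optional[dict] = None) -> str:
    lines = []
    for k in sorted(header_info or {}):
        lines.append(f"*{k}*: {header_info[k]}  ")
    lines.append("| " + " | ".join(COLUMNS) + " |")
    lines.append("|" + "---|" * len(COLUMNS))
    for r in rows:
        lines.append("| " + " | ".join(r[c] for c in COLUMNS) + " |")
    return "\n".join(lines) + "\n"


def write_report(report: ComparisonReport, path, format: str = "tsv") -> None:
    rows = report_rows(report)
    renderers = {"tsv": render_tsv, "json": render_json, "markdown": render_markdown}
    if format not in renderers:
        raise ValueError(f"unknown format {format!r} (tsv/json/markdown)")
    text = renderers[format](rows, report.header_info)
    try:
        with open(path, "w") as fh:
            fh.write(text)
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc


# -- dotplot ---------------------------------------------------------------


def dotplot(
    a: str,
    b: str,
    path=None,
    min_len: int = 20,
    a_name: str = "sequence A",
    b_name: str = "sequence B",
    coords_path=None,
):
    """Maximal-exact-match dotplot (forward matches ascending, reverse
    descending), optionally saved as an image plus a coordinate TSV."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .align import find_maximal_matches

    matches = find_maximal_matches(a, b, min_len=min_len)
    fig, ax = plt.subplots(figsize=(6, 6))
    for a_pos, b_pos, length, strand in matches:
        if strand == "+":
            ax.plot([a_pos, a_pos + length - 1], [b_pos, b_pos + length - 1],
                    color="#b22222", lw=0.8)
        else:
            ax.plot([a_pos, a_pos + length - 1], [b_pos + length - 1, b_pos],
                    color="#2222b2", lw=0.8)
    ax.set_xlabel(a_name)
    ax.set_ylabel(b_name)
    ax.set_xlim(1, len(a))
    ax.set_ylim(1, len(b))
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    plt.close(fig)
    if coords_path is not None:
        with open(coords_path, "w") as fh:
            fh.write("a_pos\tb_pos\tlength\tstrand\n")
            for m in matches:
                fh.write("\t".join(map(str, m)) + "\n")
    return matches
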