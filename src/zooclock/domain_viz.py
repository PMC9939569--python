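"""Deterministic domain-architecture diagrams.

One horizontal track per sequence at a common per-residue scale, bait
topmost, domains drawn as labeled boxes colored by accession. Output is
plain SVG text so renders are byte-stable and diff-testable.
Overlapping annotations from different databases (Pfam/SMART/CDD) are
stacked as thin sub-bars on the same track rather than merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .orf_reduce import COMPLETENESS_TAGS

# colorblind-safe cycle (Okabe-Ito) applied in sorted-accession order
PALETTE = ["#E69F00", "#56B4E9", "#009E73", "#F0E442",
           "#0072B2", "#D55E00", "#CC79A7", "#999999"]

DB_LANES = {"Pfam": 0, "SMART": 1, "CDD": 2}


@dataclass(frozen=True)
class TrackSpec:
    label: str
    length: int                      # residues
    domains: tuple[tuple[str, str, int, int, str], ...]  # (acc, name, start, end, db)
    is_bait: bool = False

    def __post_init__(self):
        for acc, name, start, end, db in self.domains:
            if not (1 <= start <= end <= self.length):
                raise ValueError(
                    f"domain {acc} [{start},{end}] outside track "
                    f"{self.label!r} of length {self.length}")


def label_candidate(species: str, seq_id: str, completeness: str,
                    phylum_code: str) -> str:
    """Display label: ``<Species> <seq_id> (<tag>) (<phylum>)``."""
    if completeness not in COMPLETENESS_TAGS:
        raise ValueError(f"unknown completeness tag {completeness!r}")
    return f"{species} {seq_id} ({completeness}) ({phylum_code})"


def label_bait(species: str, seq_id: str) -> str:
    """Bait tracks are reference proteins, not predicted ORFs, so the
    completeness parentheses are omitted."""
    return f"{species} {seq_id}"


def color_map(tracks: list[TrackSpec]) -> dict[str, str]:
    """Stable accession -> color assignment: a pure function of the
    sorted accession set across all tracks."""
    accessions = sorted({d[0] for t in tracks for d in t.domains})
    return {acc: PALETTE[i % len(PALETTE)] for i, acc in enumerate(accessions)}


def render_domain_diagram(tracks: list[TrackSpec], out_path: str | Path,
                          width: int = 900) -> None:
    """Write one SVG with one track per sequence; bait first."""
    if not tracks:
        raise ValueError("no tracks to draw")
    if any(t.is_bait for t in tracks) and not tracks[0].is_bait:
        raise ValueError("bait track must come first")
    colors = color_map(tracks)
    max_len = max(t.length for t in tracks)
    margin, label_h, track_h, gap = 20, 14, 22, 26
    scale = (width - 2 * margin) / max_len
    height = margin * 2 + len(tracks) * (label_h + track_h + gap)
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}" font-family="sans-serif" font-size="11">'
    ]
    y = margin
    for t in tracks:
        parts.append(f'<text x="{margin}" y="{y + 10}">{_esc(t.label)}</text>')
        y += label_h
        bar_w = t.length * scale
        parts.append(
            f'<rect x="{margin}" y="{y + 8}" width="{bar_w:.2f}" height="6" '
            f'fill="#cccccc"/>')
        for acc, name, start, end, db in sorted(t.domains, key=lambda d: (d[2], d[0])):
            x = margin + (start - 1) * scale
            w = (end - start + 1) * scale
            lane = DB_LANES.get(db, 0)
            box_y = y + lane * (track_h // 3)
            parts.append(
                f'<rect x="{x:.2f}" y="{box_y}" width="{w:.2f}" '
                f'height="{track_h // 3 + 2}" fill="{colors[acc]}">'
                f'<title>{_esc(f"{name} ({acc}, {db}) {start}-{end}")}</title></rect>')
        y += track_h + gap
    parts.append("</svg>")
    Path(out_path).write_text("\n".join(parts) + "\n")


def _esc(s: str) -> str:
    return (s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
             .replace('"', "&quot;"))
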