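"""Descriptive statistics over a stwintron cohort.

Covers the quantities used to characterise a catalogue of [D1,2]
stwintrons: AU permillage (1000 x (A+T)/length) with a nine-window moving
average, spacer-distance distributions between the five motifs, pyrimidine
(C/T) tracts, a 60-column junction sequence logo (15 exon + 30 concatenated
motif + 15 exon positions) and exon-context tallies at the insertion site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StwintronRecord",
    "LogoMatrix",
    "GroupSummary",
    "au_permille",
    "gc_permille",
    "moving_average_profile",
    "spacer_distances",
    "pyrimidine_tracts",
    "junction_logo",
    "exon_context_checks",
    "group_summary",
]

_GROUPS = ("sister", "sheared_sister", "UO", "other")
_PAD = "-"


@dataclass(frozen=True)
class StwintronRecord:
    """One catalogued stwintron with its motif spans and exon flanks.

    ``motif_spans`` are local half-open intervals in scan order (as in a
    scan candidate); ``flank5``/``flank3`` are up to 15 nt of the exon
    sequences immediately bordering the stwintron.
    """

    id: str
    group: str
    sequence: str
    motif_spans: tuple[tuple[str, int, int], ...]
    phase: int
    flank5: str = ""
    flank3: str = ""

    def __post_init__(self) -> None:
        if self.group not in _GROUPS:
            raise ValueError(f"group must be one of {_GROUPS}, got {self.group!r}")
        if self.phase not in (0, 1, 2):
            raise ValueError("phase must be 0, 1 or 2")
        if len(self.flank5) > 15 or len(self.flank3) > 15:
            raise ValueError("exon flanks are at most 15 nt")
        for name, s, e in self.motif_spans:
            if not (0 <= s < e <= len(self.sequence)):
                raise ValueError(f"motif span {name}:{s}-{e} outside sequence")

    def motif_span(self, label: str) -> tuple[int, int]:
        for name, s, e in self.motif_spans:
            if name == label:
                return (s, e)
        raise KeyError(label)


def au_permille(seq: str) -> float:
    """AU content in permille: 1000 x (A+T count)/length (DNA alphabet)."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    return 1000.0 * (seq.count("A") + seq.count("T")) / len(seq)


def gc_permille(seq: str) -> float:
    """GC content in permille; complements :func:`au_permille` for N-free input."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    return 1000.0 * (seq.count("G") + seq.count("C")) / len(seq)


def moving_average_profile(values: Sequence[float], window: int = 9) -> np.ndarray:
    """Centred moving average; edges average over the available span.

    Intended for histograms of integer-permille AU values binned at
    single-permille steps, but applicable to any series.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    series = pd.Series(np.asarray(values, dtype=float))
    return series.rolling(window, center=True, min_periods=1).mean().to_numpy()


_SPACER_KEYS = {
    # D-class motif order: hybrid1, internal_bp, hybrid3, external_bp, acceptor
    "internal_donor_bp": ("hybrid1", "internal_bp"),
    "internal_bp_acc": ("internal_bp", "hybrid3"),
    "external_donor_bp": ("hybrid3", "external_bp"),
    "external_bp_acc": ("external_bp", "acceptor"),
}


def spacer_distances(rec) -> dict[str, int]:
    """Distances between consecutive motifs (nt strictly between elements).

    This convention matches the bounded wildcard runs of the search
    pattern: a minimum branch-point-to-acceptor distance of 4 corresponds
    to a ``.{4,20}`` run.  Accepts a :class:`StwintronRecord` or a scan
    candidate (anything exposing ``motif_span``).
    """
    return {
        key: rec.motif_span(down)[0] - rec.motif_span(up)[1]
        for key, (up, down) in _SPACER_KEYS.items()
    }


def pyrimidine_tracts(
    seq: str,
    min_len: int = 7,
    region: str = "whole",
    motif_spans: tuple[tuple[str, int, int], ...] | None = None,
    intron: str = "external",
) -> list[tuple[int, int]]:
    """Maximal uninterrupted C/T runs of length >= ``min_len``.

    ``region`` restricts the tracts reported: ``donor_to_bp`` keeps tracts
    starting between the (relevant) donor element and the branch point,
    ``bp_to_acceptor`` between branch point and acceptor, ``whole`` keeps
    all.  A tract straddling a region boundary is assigned by its start
    position.  Region filtering needs ``motif_spans`` (D-class labels) and
    ``intron`` in {"internal", "external"}.
    """
    if region not in ("whole", "donor_to_bp", "bp_to_acceptor"):
        raise ValueError(f"unknown region {region!r}")
    seq = seq.upper()
    tracts: list[tuple[int, int]] = []
    start = None
    for i, c in enumerate(seq + "!"):  # sentinel flush
        if c in "CT":
            if start is None:
                start = i
        else:
            if start is not None and i - start >= min_len:
                tracts.append((start, i))
            start = None
    if region == "whole":
        return tracts

    if motif_spans is None:
        raise ValueError("region filtering requires motif_spans")
    spans = dict((name, (s, e)) for name, s, e in motif_spans)
    if intron == "internal":
        donor_end = spans["hybrid1"][1]
        bp = spans["internal_bp"]
        acc_start = spans["hybrid3"][0]
    elif intron == "external":
        donor_end = spans["hybrid3"][1]
        bp = spans["external_bp"]
        acc_start = spans["acceptor"][0]
    else:
        raise ValueError("intron must be 'internal' or 'external'")
    if region == "donor_to_bp":
        lo, hi = donor_end, bp[0]
    else:
        lo, hi = bp[1], acc_start
    return [(s, e) for s, e in tracts if lo <= s < hi]


@dataclass
class LogoMatrix:
    """Per-position base frequencies and information content of a junction logo.

    Columns: 15 5'-exon positions, the concatenated motifs (30 nt for
    [D1,2]), then 15 3'-exon positions.  Frequencies ignore the pad symbol
    used for flanks shorter than 15 nt; information is 2 - H(column) bits
    (optionally with the small-sample correction subtracted).
    """

    frequencies: pd.DataFrame  # columns A, C, G, T; one row per position
    information: np.ndarray  # bits, len == positions
    counts: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_positions(self) -> int:
        return len(self.frequencies)


def _logo_rows(records: Sequence[StwintronRecord]) -> list[str]:
    rows = []
    for rec in records:
        motifs = "".join(rec.sequence[s:e] for _, s, e in rec.motif_spans)
        flank5 = rec.flank5.rjust(15, _PAD)
        flank3 = rec.flank3.ljust(15, _PAD)
        rows.append(flank5 + motifs + flank3)
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError("records mix motif layouts of different total width")
    return rows


def junction_logo(
    records: Sequence[StwintronRecord], small_sample_correction: bool = False
) -> LogoMatrix:
    """Stack flank + concatenated-motif sequences into a logo matrix.

    For a [D1,2] cohort the layout is 60 columns and column 16 (1-based) is
    the invariant G1 of the split external donor: information 2 bits when
    every record complies.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records for a logo")
    rows = _logo_rows(records)
    n_pos = len(rows[0])
    bases = list("ACGT")
    counts = pd.DataFrame(0, index=range(n_pos), columns=bases, dtype=int)
    for row in rows:
        for i, c in enumerate(row):
            if c in counts.columns:
                counts.loc[i, c] += 1
    totals = counts.sum(axis=1)
    freqs = counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    info = np.zeros(n_pos)
    for i in range(n_pos):
        p = freqs.iloc[i].to_numpy()
        h = -sum(x * math.log2(x) for x in p if x > 0)
        e_corr = 0.0
        if small_sample_correction and totals.iloc[i] > 0:
            e_corr = 3.0 / (2.0 * math.log(2) * totals.iloc[i])
        info[i] = max(0.0, 2.0 - h - e_corr) if totals.iloc[i] > 0 else 0.0
    return LogoMatrix(frequencies=freqs, information=info, counts=counts)


def exon_context_checks(records: Iterable[StwintronRecord]) -> dict[str, int]:
    """Tallies of diagnostic exon contexts at the insertion site.

    * ``ag_up_and_gt_down``: AG immediately upstream AND GT immediately
      downstream (a pseudo double AG|GT fusion site);
    * ``tag_up`` / ``cag_up``: 3-mer directly upstream;
    * ``gt_down`` / ``gta_down``: 2-/3-mer directly downstream;
    * ``g_down``: downstream starts with G (the [A2,3]-alternative trigger).
    """
    tally = dict.fromkeys(
        ("ag_up_and_gt_down", "tag_up", "cag_up", "gt_down", "gta_down", "g_down"), 0
    )
    for rec in records:
        up, down = rec.flank5.upper(), rec.flank3.upper()
        if up.endswith("AG") and down.startswith("GT"):
            tally["ag_up_and_gt_down"] += 1
        if up.endswith("TAG"):
            tally["tag_up"] += 1
        if up.endswith("CAG"):
            tally["cag_up"] += 1
        if down.startswith("GT"):
            tally["gt_down"] += 1
        if down.startswith("GTA"):
            tally["gta_down"] += 1
        if down.startswith("G"):
            tally["g_down"] += 1
    return tally


@dataclass
class GroupSummary:
    """Per-group cohort summary plus the fraction-ordered AU curves."""

    table: pd.DataFrame
    au_curves: dict[str, pd.DataFrame]
    au_at_half: dict[str, float]


def group_summary(
    records: Sequence[StwintronRecord],
    group_field: str = "group",
    window: int = 9,
) -> GroupSummary:
    """Summarise a cohort per group.

    The table reports n, AU permillage mean/min/max, length extremes,
    phase proportions and the modal spacer distances.  ``au_curves`` holds,
    per group, the moving average of the sorted AU values against the
    stwintron fraction; ``au_at_half`` interpolates that curve at fraction
    0.5 (the "mean" of the fraction plot, reported alongside the
    arithmetic mean because the two need not coincide).
    """
    if not records:
        raise ValueError("empty cohort")
    groups: dict[str, list[StwintronRecord]] = {}
    for rec in records:
        groups.setdefault(getattr(rec, group_field), []).append(rec)

    rows = []
    curves: dict[str, pd.DataFrame] = {}
    at_half: dict[str, float] = {}
    for gname, recs in sorted(groups.items()):
        au = np.array([au_permille(r.sequence) for r in recs])
        lengths = np.array([len(r.sequence) for r in recs])
        phases = np.array([r.phase for r in recs])
        dists = [spacer_distances(r) for r in recs]
        modes = {
            key: int(pd.Series([d[key] for d in dists]).mode().iloc[0])
            for key in _SPACER_KEYS
        }
        row = {
            "group": gname,
            "n": len(recs),
            "au_mean": float(au.mean()),
            "au_min": float(au.min()),
            "au_max": float(au.max()),
            "len_min": int(lengths.min()),
            "len_max": int(lengths.max()),
            "phase0": float((phases == 0).mean()),
            "phase1": float((phases == 1).mean()),
            "phase2": float((phases == 2).mean()),
        }
        row.update({f"mode_{k}": v for k, v in modes.items()})
        rows.append(row)

        ordered = np.sort(au)
        smoothed = moving_average_profile(ordered, window=min(window, 2 * len(ordered) - 1))
        frac = (np.arange(len(ordered)) + 0.5) / len(ordered)
        curves[gname] = pd.DataFrame({"fraction": frac, "au_smoothed": smoothed})
        at_half[gname] = float(np.interp(0.5, frac, smoothed))

    return GroupSummary(
        table=pd.DataFrame(rows).set_index("group"),
        au_curves=curves,
        au_at_half=at_half,
    )
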