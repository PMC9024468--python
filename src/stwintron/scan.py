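"""Scan genomic contigs with a stwintron search model.

Two scan modes are provided.  ``greedy`` emulates a conventional regular
expression engine: leftmost, non-overlapping matches with greedy (longest
first) spacer runs — the behaviour of the web pattern-search tools used for
whole-genome screens.  ``exhaustive`` enumerates every distinct
(start, motif-placement) tuple that satisfies the model's constraints,
overlapping matches included; its output is a superset of greedy mode and is
cross-checked against a brute-force placement oracle in the test suite.

Coordinates are 0-based half-open throughout the API; the GFF3 writer emits
the conventional 1-based inclusive columns.
"""

from __future__ import annotations

import csv
import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

from stwintron.models import IUPAC, MotifToken, StwintronSearchModel
from stwintron.symmetry import reverse_complement

__all__ = [
    "StwintronCandidate",
    "ScanReport",
    "scan_sequence",
    "scan_genome",
    "write_candidates",
    "read_candidates",
]

_MOTIF_LABELS = ("hybrid1", "internal_bp", "hybrid3", "external_bp", "acceptor")


@dataclass(frozen=True)
class StwintronCandidate:
    """One genomic stwintron match.

    ``start``/``end`` are a half-open interval on the + strand of the
    contig; ``motif_spans`` are half-open intervals in stwintron-local
    coordinates (i.e. relative to ``sequence``, which is given in reading
    orientation — for minus-strand candidates this is the reverse
    complement of the + strand slice).
    """

    contig_id: str
    strand: str
    start: int
    end: int
    motif_spans: tuple[tuple[str, int, int], ...]
    sequence: str
    model_names: tuple[str, ...]
    stw_type: str = "D12"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("sequence length does not match span")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def motif_span(self, label: str) -> tuple[int, int]:
        for name, s, e in self.motif_spans:
            if name == label:
                return (s, e)
        raise KeyError(label)

    @property
    def internal_intron_span(self) -> tuple[int, int]:
        """Local span of the internal intron.

        For a [Dn,n+1] candidate this runs from position n (after the
        external-donor head of the 5' hybrid) to the end of the acceptor
        part of the 3' hybrid.
        """
        if self.stw_type.startswith("D"):
            n = int(self.stw_type[1])
            h3_start = self.motif_span("hybrid3")[0]
            return (n, h3_start + 3)
        # A23: internal intron starts after the HA head of the hybrid
        # acceptor motif and ends after its own 3'-acceptor.
        ha_start = self.motif_span("hybrid_acc")[0]
        acc3_start = self.motif_span("acceptor3")[0]
        return (ha_start + 2, acc3_start + 3)

    @property
    def external_intron_parts(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """The two local intervals of the (split) external intron."""
        i0, i1 = self.internal_intron_span
        return ((0, i0), (i1, len(self.sequence)))


@dataclass
class ScanReport:
    """Candidates plus per-contig / per-model tallies for one scan run."""

    candidates: list[StwintronCandidate] = field(default_factory=list)
    mode: str = "greedy"

    @property
    def per_contig(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.candidates:
            out[c.contig_id] = out.get(c.contig_id, 0) + 1
        return out

    @property
    def per_model(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.candidates:
            for m in c.model_names:
                out[m] = out.get(m, 0) + 1
        return out

    def __len__(self) -> int:
        return len(self.candidates)


# ---------------------------------------------------------------------------
# matching machinery

def _validate_subject(seq: str) -> str:
    seq = seq.upper()
    bad = [i for i, c in enumerate(seq) if c not in "ACGTN"]
    if bad:
        head = ", ".join(str(i) for i in bad[:10])
        more = "" if len(bad) <= 10 else f" (+{len(bad) - 10} more)"
        raise ValueError(f"invalid characters at positions {head}{more}")
    return seq


def _alt_regex(alt: str) -> str:
    out = []
    for code in alt:
        bases = sorted(IUPAC[code])
        out.append(bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]")
    return "".join(out)


def _compile_greedy(model: StwintronSearchModel) -> re.Pattern[str]:
    """Compile the model into a grouped regex (spacers restricted to ACGT)."""
    parts = []
    ranges = model.spacer_ranges()
    for i, token in enumerate(model.motifs()):
        alt = "|".join(_alt_regex(a) for a in token.alternatives)
        parts.append(f"({alt})")
        if i < 4:
            lo, hi = ranges[i]
            parts.append(f"([ACGT]{{{lo},{hi}}})")
    return re.compile("".join(parts))


def _motif_positions(seq: str, token: MotifToken) -> list[int]:
    """All positions where the motif matches, via alternation regex with overlap."""
    pattern = re.compile("(?=(?:" + "|".join(_alt_regex(a) for a in token.alternatives) + "))")
    return [m.start() for m in pattern.finditer(seq)]


def _spans_from_positions(
    positions: tuple[int, ...], motifs: Sequence[MotifToken]
) -> tuple[tuple[str, int, int], ...]:
    base = positions[0]
    labels = (
        _MOTIF_LABELS
        if motifs[0].name == "hybrid1"
        else tuple(m.name for m in motifs)
    )
    return tuple(
        (label, p - base, p - base + m.length)
        for label, p, m in zip(labels, positions, motifs)
    )


def _has_n(n_prefix: list[int], start: int, end: int) -> bool:
    return n_prefix[end] - n_prefix[start] > 0


def _exhaustive_placements(
    seq: str, model: StwintronSearchModel
) -> Iterator[tuple[int, ...]]:
    """Yield every (p1..p5) motif-placement tuple satisfying the model.

    Works by precomputing, for each motif, the sorted list of positions at
    which it matches, then joining the lists under the spacer-range
    constraints (binary search per level).  This is algorithmically distinct
    from — and verified against — a naive per-start nested spacer
    enumeration.
    """
    motifs = model.motifs()
    ranges = model.spacer_ranges()
    occ = [_motif_positions(seq, m) for m in motifs]
    if not all(occ):
        return

    def extend(prefix: tuple[int, ...], level: int) -> Iterator[tuple[int, ...]]:
        if level == 5:
            yield prefix
            return
        prev_end = prefix[-1] + motifs[level - 1].length
        lo, hi = ranges[level - 1]
        cand = occ[level]
        i = bisect_left(cand, prev_end + lo)
        j = bisect_right(cand, prev_end + hi)
        for p in cand[i:j]:
            yield from extend(prefix + (p,), level + 1)

    for p1 in occ[0]:
        yield from extend((p1,), 1)


def scan_sequence(
    seq: str,
    model: StwintronSearchModel,
    mode: str = "greedy",
    contig_id: str = "seq",
    strand: str = "+",
) -> list[StwintronCandidate]:
    """Scan one nucleotide string and return stwintron candidates.

    ``mode="greedy"`` returns leftmost non-overlapping matches with greedy
    spacer runs; ``mode="exhaustive"`` returns every satisfying motif
    placement (overlaps allowed).  Candidates whose span contains an ``N``
    are suppressed in both modes.
    """
    if mode not in ("greedy", "exhaustive"):
        raise ValueError(f"unknown scan mode {mode!r}; use 'greedy' or 'exhaustive'")
    seq = _validate_subject(seq)
    motifs = model.motifs()
    n_prefix = [0]
    for c in seq:
        n_prefix.append(n_prefix[-1] + (c == "N"))

    out: list[StwintronCandidate] = []
    if mode == "greedy":
        pat = _compile_greedy(model)
        for m in pat.finditer(seq):
            start, end = m.start(), m.end()
            if _has_n(n_prefix, start, end):
                continue
            positions = tuple(m.start(2 * i + 1) for i in range(5))
            out.append(
                StwintronCandidate(
                    contig_id=contig_id,
                    strand=strand,
                    start=start,
                    end=end,
                    motif_spans=_spans_from_positions(
                        tuple(p - start for p in positions), motifs
                    ),
                    sequence=seq[start:end],
                    model_names=(model.name,),
                    stw_type=model.stw_type,
                )
            )
        return out

    for placement in _exhaustive_placements(seq, model):
        start = placement[0]
        end = placement[4] + motifs[4].length
        if _has_n(n_prefix, start, end):
            continue
        out.append(
            StwintronCandidate(
                contig_id=contig_id,
                strand=strand,
                start=start,
                end=end,
                motif_spans=_spans_from_positions(
                    tuple(p - start for p in placement), motifs
                ),
                sequence=seq[start:end],
                model_names=(model.name,),
                stw_type=model.stw_type,
            )
        )
    out.sort(key=lambda c: (c.start, c.end, c.motif_spans))
    return out


def _to_plus_strand(cand: StwintronCandidate, contig_len: int) -> StwintronCandidate:
    """Re-express a candidate found on the reverse complement in + coordinates."""
    return StwintronCandidate(
        contig_id=cand.contig_id,
        strand="-",
        start=contig_len - cand.end,
        end=contig_len - cand.start,
        motif_spans=cand.motif_spans,  # local coords, reading orientation
        sequence=cand.sequence,
        model_names=cand.model_names,
        stw_type=cand.stw_type,
    )


def _iter_contigs(contigs) -> Iterator[tuple[str, str]]:
    if isinstance(contigs, (str, Path)):
        records = list(SeqIO.parse(str(contigs), "fasta"))
        if not records:
            raise ValueError(f"no FASTA records found in {contigs}")
        for rec in records:
            yield rec.id, str(rec.seq)
    elif isinstance(contigs, dict):
        yield from contigs.items()
    else:
        for rec in contigs:
            if hasattr(rec, "seq"):
                yield rec.id, str(rec.seq)
            else:
                yield rec  # (id, seq) tuple


def scan_genome(
    contigs,
    models: Sequence[StwintronSearchModel],
    strands: str = "both",
    mode: str = "greedy",
) -> ScanReport:
    """Scan FASTA contigs with one or more models.

    ``contigs`` may be a FASTA path, a mapping of id to sequence, or an
    iterable of SeqRecords / (id, sequence) pairs.  Minus-strand candidates
    are reported with their + strand genomic span and ``strand="-"``.
    Candidates found by several models are deduplicated on
    (contig, strand, span), keeping all model labels.  Output order is
    (contig, start, strand).
    """
    if strands not in ("+", "-", "both"):
        raise ValueError(f"strands must be '+', '-' or 'both', got {strands!r}")
    if not models:
        raise ValueError("at least one search model is required")

    merged: dict[tuple[str, str, int, int], StwintronCandidate] = {}
    seen_ids: set[str] = set()
    n_contigs = 0
    for contig_id, seq in _iter_contigs(contigs):
        n_contigs += 1
        if contig_id in seen_ids:
            raise ValueError(f"duplicate contig ID {contig_id!r}")
        seen_ids.add(contig_id)
        seq = _validate_subject(seq)
        rc = reverse_complement(seq) if strands in ("-", "both") else ""
        for model in models:
            found: list[StwintronCandidate] = []
            if strands in ("+", "both"):
                found.extend(scan_sequence(seq, model, mode, contig_id, "+"))
            if strands in ("-", "both"):
                found.extend(
                    _to_plus_strand(c, len(seq))
                    for c in scan_sequence(rc, model, mode, contig_id, "+")
                )
            for cand in found:
                key = (cand.contig_id, cand.strand, cand.start, cand.end)
                prev = merged.get(key)
                if prev is None:
                    merged[key] = cand
                elif cand.model_names[0] not in prev.model_names:
                    merged[key] = StwintronCandidate(
                        contig_id=prev.contig_id,
                        strand=prev.strand,
                        start=prev.start,
                        end=prev.end,
                        motif_spans=prev.motif_spans,
                        sequence=prev.sequence,
                        model_names=prev.model_names + cand.model_names,
                        stw_type=prev.stw_type,
                    )
    if n_contigs == 0:
        raise ValueError("empty contig source")

    report = ScanReport(mode=mode)
    report.candidates = sorted(
        merged.values(), key=lambda c: (c.contig_id, c.start, c.strand)
    )
    return report


# ---------------------------------------------------------------------------
# writers / readers

_TSV_FIELDS = [
    "contig", "strand", "start", "end", "model_names", "stw_type",
    "motif_spans", "sequence",
]


def _motif_spans_str(cand: StwintronCandidate) -> str:
    return ";".join(f"{name}:{s}-{e}" for name, s, e in cand.motif_spans)


def _parse_motif_spans(text: str) -> tuple[tuple[str, int, int], ...]:
    out = []
    for item in text.split(";"):
        name, span = item.split(":")
        s, e = span.split("-")
        out.append((name, int(s), int(e)))
    return tuple(out)


def write_candidates(report: ScanReport, path: str | Path, format: str = "tsv") -> Path:
    """Write a scan report as GFF3, BED or TSV.

    GFF3 uses 1-based inclusive coordinates with a ``stwintron`` parent
    feature and one child feature per motif; BED is 0-based half-open;
    TSV carries every field (including local motif coordinates and the
    spanned sequence) and round-trips via :func:`read_candidates`.
    """
    path = Path(path)
    if format == "tsv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(_TSV_FIELDS)
            for c in report.candidates:
                writer.writerow([
                    c.contig_id, c.strand, c.start, c.end,
                    ",".join(c.model_names), c.stw_type,
                    _motif_spans_str(c), c.sequence,
                ])
        return path
    if format == "bed":
        with path.open("w") as fh:
            fh.write('track name="stwintron" description="stwintron candidates"\n')
            for i, c in enumerate(report.candidates):
                fh.write(
                    f"{c.contig_id}\t{c.start}\t{c.end}\tstw_{i + 1}\t0\t{c.strand}\n"
                )
        return path
    if format == "gff3":
        with path.open("w") as fh:
            fh.write("##gff-version 3\n")
            for i, c in enumerate(report.candidates):
                attrs = (
                    f"ID=stw_{i + 1};models={','.join(c.model_names)};"
                    f"stw_type={c.stw_type};seq={c.sequence}"
                )
                fh.write(
                    f"{c.contig_id}\tstwintron\tstwintron\t{c.start + 1}\t{c.end}"
                    f"\t.\t{c.strand}\t.\t{attrs}\n"
                )
                for name, s, e in c.motif_spans:
                    # local spans are in reading orientation
                    if c.strand == "+":
                        gs, ge = c.start + s, c.start + e
                    else:
                        gs, ge = c.end - e, c.end - s
                    fh.write(
                        f"{c.contig_id}\tstwintron\tmotif\t{gs + 1}\t{ge}\t.\t"
                        f"{c.strand}\t.\tID=stw_{i + 1}.{name};Parent=stw_{i + 1};"
                        f"motif={name}\n"
                    )
        return path
    raise ValueError(f"unknown format {format!r}; use 'gff3', 'bed' or 'tsv'")


def read_candidates(path: str | Path, format: str = "tsv", mode: str = "greedy") -> ScanReport:
    """Read candidates back from a TSV or GFF3 file written by :func:`write_candidates`."""
    path = Path(path)
    report = ScanReport(mode=mode)
    if format == "tsv":
        with path.open() as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                report.candidates.append(
                    StwintronCandidate(
                        contig_id=row["contig"],
                        strand=row["strand"],
                        start=int(row["start"]),
                        end=int(row["end"]),
                        motif_spans=_parse_motif_spans(row["motif_spans"]),
                        sequence=row["sequence"],
                        model_names=tuple(row["model_names"].split(",")),
                        stw_type=row["stw_type"],
                    )
                )
        return report
    if format == "gff3":
        with path.open() as fh:
            pending: dict[str, dict] = {}
            order: list[str] = []
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                cols = line.rstrip("\n").split("\t")
                if cols[2] != "stwintron":
                    continue
                attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
                pending[attrs["ID"]] = {
                    "contig": cols[0],
                    "start": int(cols[3]) - 1,
                    "end": int(cols[4]),
                    "strand": cols[6],
                    "models": tuple(attrs["models"].split(",")),
                    "stw_type": attrs.get("stw_type", "D12"),
                    "seq": attrs.get("seq", ""),
                    "motifs": [],
                }
                order.append(attrs["ID"])
            fh.seek(0)
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                cols = line.rstrip("\n").split("\t")
                if cols[2] != "motif":
                    continue
                attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv)
                parent = pending[attrs["Parent"]]
                gs, ge = int(cols[3]) - 1, int(cols[4])
                if parent["strand"] == "+":
                    s, e = gs - parent["start"], ge - parent["start"]
                else:
                    s, e = parent["end"] - ge, parent["end"] - gs
                parent["motifs"].append((attrs["motif"], s, e))
        for key in order:
            rec = pending[key]
            report.candidates.append(
                StwintronCandidate(
                    contig_id=rec["contig"],
                    strand=rec["strand"],
                    start=rec["start"],
                    end=rec["end"],
                    motif_spans=tuple(sorted(rec["motifs"], key=lambda t: t[1])),
                    sequence=rec["seq"],
                    model_names=rec["models"],
                    stw_type=rec["stw_type"],
                )
            )
        return report
    raise ValueError(f"unknown format {format!r}; use 'tsv' or 'gff3'")
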