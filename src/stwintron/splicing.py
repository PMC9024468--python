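"""Splicing geometry of a stwintron in gene context.

A [D1,2] stwintron begins with the G1 of the split external donor; the
internal intron (starting at the stwintron's second base) must be excised
first, reconstituting the external donor (G1 joined to its U2RWGY tail).
The resulting intermediate — the *splinter* — still carries the external
intron, whose excision fuses the exons.  Direct pairing of the distal
splice sites instead removes everything but the G1 in a single reaction,
leaving one extra exonic base and a +1 frameshift.

The same intervening sequence can alternatively be read as an [A2,3]
stwintron shifted one nucleotide 3' whenever the first exonic base
downstream is a G (5'-HAG|G); both splicing paths then yield identical
mature mRNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from stwintron.models import DONOR_SET_24
from stwintron.scan import StwintronCandidate
from stwintron.symmetry import reverse_complement

__all__ = [
    "GeneContext",
    "SpliceProducts",
    "JunctionQueries",
    "ReadEvidence",
    "splice",
    "phase",
    "a23_alternative",
    "build_queries",
    "validate_reads",
]


@dataclass(frozen=True)
class GeneContext:
    """A stwintron between two exon fragments.

    ``internal_span`` is the half-open local span of the internal intron
    within ``stwintron``; for a [D1,2] it starts at 1 (after the G1).
    ``split_point`` is the number of external-donor nucleotides 5' of the
    internal intron (1 for [D1,2], 5 for a morphed [D5,6]).
    ``cds_offset_before`` is the reading-frame offset of the insertion
    point (0 between codons, 1 after the first codon base, 2 after the
    second). ``donor_universe`` lists the 6-mers accepted as a functional
    reconstituted external donor.
    """

    upstream_exon: str
    stwintron: str
    downstream_exon: str
    internal_span: tuple[int, int] | None = None
    cds_offset_before: int = 0
    split_point: int = 1
    donor_universe: tuple[str, ...] = DONOR_SET_24

    def __post_init__(self) -> None:
        for label, seq in (
            ("upstream_exon", self.upstream_exon),
            ("downstream_exon", self.downstream_exon),
        ):
            if any(c not in "ACGT" for c in seq.upper()):
                raise ValueError(f"{label} must be over ACGT")
        if self.cds_offset_before not in (0, 1, 2):
            raise ValueError("cds_offset_before must be 0, 1 or 2")
        if self.internal_span is None:
            object.__setattr__(self, "internal_span", self._infer_internal_span())
        i0, i1 = self.internal_span
        if not (0 < i0 < i1 <= len(self.stwintron)):
            raise ValueError(f"internal_span {self.internal_span} outside stwintron")
        if i0 != self.split_point:
            raise ValueError(
                f"internal intron must start at the donor split point "
                f"({self.split_point}), got {i0}"
            )

    def _infer_internal_span(self) -> tuple[int, int]:
        raise ValueError(
            "internal_span is required when the stwintron is given as a raw sequence"
        )

    @classmethod
    def from_candidate(
        cls,
        candidate: StwintronCandidate,
        upstream_exon: str,
        downstream_exon: str,
        cds_offset_before: int = 0,
        donor_universe: tuple[str, ...] = DONOR_SET_24,
    ) -> "GeneContext":
        if not candidate.stw_type.startswith("D"):
            raise NotImplementedError(
                "gene-context splicing is defined for [D]-class candidates"
            )
        split = int(candidate.stw_type[1])
        return cls(
            upstream_exon=upstream_exon,
            stwintron=candidate.sequence,
            downstream_exon=downstream_exon,
            internal_span=candidate.internal_intron_span,
            cds_offset_before=cds_offset_before,
            split_point=split,
            donor_universe=donor_universe,
        )

    @property
    def external_intron(self) -> str:
        """External intron as reconstituted after internal excision."""
        i0, i1 = self.internal_span
        return self.stwintron[:i0] + self.stwintron[i1:]


@dataclass(frozen=True)
class SpliceProducts:
    """The four RNA species of a stwintron gene (DNA alphabet)."""

    pre_mrna: str
    splinter: str
    mature: str
    one_step: str
    frameshift_of_one_step: int


@dataclass(frozen=True)
class JunctionQueries:
    """60-nt validation queries centred on the two diagnostic junctions.

    ``exon_fusion_query`` spans the predicted exon/exon fusion of mature
    mRNA; ``splinter_query`` spans the junction of the upstream exon and
    the reconstituted external intron in the splinter intermediate.
    ``junction_at`` gives the offset of each junction within its query
    (equal to the flank size unless truncated).
    """

    exon_fusion_query: str
    splinter_query: str
    junction_at: tuple[int, int]
    truncated: bool


@dataclass(frozen=True)
class ReadEvidence:
    """Outcome of matching a read set against the two junction queries."""

    mature_read_ids: tuple[str, ...]
    splinter_read_ids: tuple[str, ...]
    isoform_call: str  # mature-supported | splinter-supported | both | none


def splice(gene: GeneContext) -> SpliceProducts:
    """Run the two-step excision and the one-step mis-splice.

    Raises ``ValueError("external donor not reconstituted")`` when removing
    the internal intron does not expose a 6-mer from the gene's donor
    universe at the start of the external intron.
    """
    ext = gene.external_intron
    if ext[:6] not in gene.donor_universe:
        raise ValueError(
            f"external donor not reconstituted: {ext[:6]!r} is not in the donor universe"
        )
    up, down = gene.upstream_exon, gene.downstream_exon
    pre = up + gene.stwintron + down
    splinter = up + ext + down
    mature = up + down
    head = gene.stwintron[: gene.internal_span[0]]  # G1 for [D1,2]
    one_step = up + head + down
    return SpliceProducts(
        pre_mrna=pre,
        splinter=splinter,
        mature=mature,
        one_step=one_step,
        frameshift_of_one_step=len(head) % 3,
    )


def phase(gene: GeneContext) -> int:
    """Intron phase: position of the insertion point within the codon."""
    return gene.cds_offset_before


def a23_alternative(gene: GeneContext) -> bool:
    """Whether the [D1,2] can alternatively be excised as an [A2,3].

    The [A2,3] reading shifts the intervening sequence one nucleotide 3'
    (the leading G becomes exonic, the first downstream base joins the
    intron); it exists exactly when the first downstream exonic base is G,
    and then both splicing paths give identical mature mRNA (asserted).
    """
    if gene.split_point != 1:
        raise ValueError("the [A2,3] alternative is defined for [D1,2] geometry")
    if not gene.downstream_exon.startswith("G"):
        return False
    mature_d12 = gene.upstream_exon + gene.downstream_exon
    # shifted reading: exon gains the stwintron's G1, intron gains the downstream G
    mature_a23 = gene.upstream_exon + gene.stwintron[0] + gene.downstream_exon[1:]
    assert mature_a23 == mature_d12, "alternative [A2,3] reading must restore the same mRNA"
    return True


def build_queries(gene: GeneContext, flank: int = 30) -> JunctionQueries:
    """Build the two junction queries (default 30 nt each side, 60 nt total).

    Exons shorter than the flank truncate the query; the result is flagged.
    """
    up = gene.upstream_exon[-flank:]
    down = gene.downstream_exon[:flank]
    ext_head = (gene.external_intron + gene.downstream_exon)[:flank]
    truncated = len(up) < flank or len(down) < flank
    return JunctionQueries(
        exon_fusion_query=up + down,
        splinter_query=up + ext_head,
        junction_at=(len(up), len(up)),
        truncated=truncated,
    )


def _reads_as_pairs(reads) -> Iterable[tuple[str, str]]:
    if isinstance(reads, Mapping):
        return list(reads.items())
    out = []
    for i, r in enumerate(reads):
        if hasattr(r, "seq"):
            out.append((r.id, str(r.seq)))
        elif isinstance(r, tuple):
            out.append(r)
        else:
            out.append((f"read_{i + 1}", str(r)))
    return out


def validate_reads(
    queries: JunctionQueries,
    reads,
    k: int = 10,
) -> ReadEvidence:
    """Match reads (either orientation, exact substring) against the queries.

    A query is supported when some read contains the query window spanning
    the junction by at least ``k`` nt on each side.  Reads may be a mapping
    id->sequence, SeqRecords, (id, sequence) pairs or bare strings.
    """
    pairs = _reads_as_pairs(reads)

    def supporters(query: str, junction: int) -> tuple[str, ...]:
        lo, hi = junction - k, junction + k
        if lo < 0 or hi > len(query):
            return ()
        core = query[lo:hi]
        hits = []
        for rid, seq in pairs:
            seq = seq.upper()
            if core in seq or core in reverse_complement(seq):
                hits.append(rid)
        return tuple(hits)

    mature_ids = supporters(queries.exon_fusion_query, queries.junction_at[0])
    splinter_ids = supporters(queries.splinter_query, queries.junction_at[1])
    if mature_ids and splinter_ids:
        call = "both"
    elif mature_ids:
        call = "mature-supported"
    elif splinter_ids:
        call = "splinter-supported"
    else:
        call = "none"
    return ReadEvidence(
        mature_read_ids=mature_ids,
        splinter_read_ids=splinter_ids,
        isoform_call=call,
    )
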