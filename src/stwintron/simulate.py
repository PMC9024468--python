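"""Ground-truthed synthetic genomes, stwintron genes and read sets.

Every other module is testable without downloads: this module builds
random genomic background of configurable GC content, plants
model-compliant stwintrons (with exact truth coordinates) into it, and
draws error-free 100-nt reads from the four transcript isoforms
(pre-mRNA, splinter, mature, one-step mis-splice).

A single integer seed governs all randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from stwintron.models import StwintronSearchModel, expand_iupac, preset_model
from stwintron.scan import ScanReport, StwintronCandidate, scan_sequence, write_candidates
from stwintron.splicing import GeneContext, splice
from stwintron.symmetry import reverse_complement

__all__ = [
    "PlantSpec",
    "AnnotatedStwintron",
    "SyntheticGene",
    "TruthSet",
    "SimRead",
    "random_background",
    "make_stwintron",
    "make_gene",
    "plant",
    "simulate_reads",
]

_ISOFORMS = ("pre", "splinter", "mature", "one_step")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_background(length: int, gc: float = 0.45, seed=0) -> str:
    """I.i.d. random DNA with P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = _rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(np.array(list("ACGT")), size=length, p=probs))


@dataclass(frozen=True)
class PlantSpec:
    """Concrete instantiation choices for one planted stwintron.

    ``spacers`` are the four spacer lengths in scan order (internal
    donor-BP, internal BP-acceptor, external donor-BP, external
    BP-acceptor for D-class models).  Spacer lengths outside the model's
    ranges are rejected unless ``allow_out_of_range`` is set (used for
    negative-control fixtures).
    """

    model: StwintronSearchModel
    internal_donor: str
    external_donor: str
    internal_bp: str
    external_bp: str
    internal_acceptor: str
    external_acceptor: str
    spacers: tuple[int, int, int, int]
    gc: float = 0.45
    phase: int = 1
    allow_out_of_range: bool = False

    def __post_init__(self) -> None:
        m = self.model
        if not m.stw_type.startswith("D"):
            raise NotImplementedError("the generator plants [D]-class stwintrons")
        for label, motif, universe in (
            ("internal_donor", self.internal_donor, set(m.internal.donors)),
            ("external_donor", self.external_donor, set(m.external.donors)),
            ("internal_bp", self.internal_bp, expand_iupac(m.internal.bp_motif)),
            ("external_bp", self.external_bp, expand_iupac(m.external.bp_motif)),
            ("internal_acceptor", self.internal_acceptor, expand_iupac(m.internal.acceptor_motif)),
            ("external_acceptor", self.external_acceptor, expand_iupac(m.external.acceptor_motif)),
        ):
            if motif not in universe:
                raise ValueError(f"{label} {motif!r} is not admitted by model {m.name!r}")
        if not self.allow_out_of_range:
            for val, (lo, hi) in zip(self.spacers, m.spacer_ranges()):
                if not lo <= val <= hi:
                    raise ValueError(
                        f"spacer length {val} outside model range {lo}-{hi} "
                        "(set allow_out_of_range for negative controls)"
                    )

    @classmethod
    def random(
        cls, model: StwintronSearchModel | str, seed=0, gc: float = 0.45, phase: int | None = None
    ) -> "PlantSpec":
        """Draw a uniform compliant instantiation from the model's element sets."""
        if isinstance(model, str):
            model = preset_model(model)
        rng = _rng(seed)

        def pick(options) -> str:
            options = sorted(options)
            return options[rng.integers(len(options))]

        spacers = tuple(int(rng.integers(lo, hi + 1)) for lo, hi in model.spacer_ranges())
        return cls(
            model=model,
            internal_donor=pick(model.internal.donors),
            external_donor=pick(model.external.donors),
            internal_bp=pick(expand_iupac(model.internal.bp_motif)),
            external_bp=pick(expand_iupac(model.external.bp_motif)),
            internal_acceptor=pick(expand_iupac(model.internal.acceptor_motif)),
            external_acceptor=pick(expand_iupac(model.external.acceptor_motif)),
            spacers=spacers,
            gc=gc,
            phase=int(rng.integers(0, 3)) if phase is None else phase,
        )


@dataclass(frozen=True)
class AnnotatedStwintron:
    """A generated stwintron sequence with exact local motif spans."""

    sequence: str
    motif_spans: tuple[tuple[str, int, int], ...]
    spec: PlantSpec

    def motif_span(self, label: str) -> tuple[int, int]:
        for name, s, e in self.motif_spans:
            if name == label:
                return (s, e)
        raise KeyError(label)

    @property
    def internal_span(self) -> tuple[int, int]:
        n = self.spec.model.donor_split
        h3 = self.motif_span("hybrid3")
        return (n, h3[0] + 3)


def _assemble(spec: PlantSpec, spacer_seqs: tuple[str, ...]) -> AnnotatedStwintron:
    m = spec.model
    n = m.donor_split
    head = spec.external_donor[:n]
    tail = spec.external_donor[n:]
    pieces = [
        ("hybrid1", head + spec.internal_donor),
        (None, spacer_seqs[0]),
        ("internal_bp", spec.internal_bp),
        (None, spacer_seqs[1]),
        ("hybrid3", spec.internal_acceptor + tail),
        (None, spacer_seqs[2]),
        ("external_bp", spec.external_bp),
        (None, spacer_seqs[3]),
        ("acceptor", spec.external_acceptor),
    ]
    seq_parts: list[str] = []
    spans: list[tuple[str, int, int]] = []
    pos = 0
    for name, part in pieces:
        if name is not None:
            spans.append((name, pos, pos + len(part)))
        seq_parts.append(part)
        pos += len(part)
    return AnnotatedStwintron("".join(seq_parts), tuple(spans), spec)


def make_stwintron(
    spec: PlantSpec,
    seed=0,
    clean: bool = True,
    max_retries: int = 1000,
    clean_against: tuple[StwintronSearchModel, ...] = (),
) -> AnnotatedStwintron:
    """Generate a stwintron obeying the spec, with random spacer fill.

    With ``clean=True`` (default) spacer sequences are rejection-sampled
    until an exhaustive scan of the stwintron with its own model yields
    exactly one candidate — the planted one — so no accidental alternative
    motif placement exists inside the sequence.  ``clean_against`` lists
    further models that must find nothing at all (used for
    model-discrimination fixtures, e.g. a widened-spacer stwintron that a
    narrower model must not see).  A retry cap guards against
    non-termination at extreme GC.
    """
    rng = _rng(seed)
    for _ in range(max_retries):
        spacer_seqs = tuple(
            random_background(length, spec.gc, rng) for length in spec.spacers
        )
        stw = _assemble(spec, spacer_seqs)
        if not clean:
            return stw
        if any(
            scan_sequence(stw.sequence, other, mode="exhaustive")
            for other in clean_against
        ):
            continue
        if spec.allow_out_of_range:
            return stw  # deliberately non-compliant: nothing to verify by scan
        hits = scan_sequence(stw.sequence, spec.model, mode="exhaustive")
        if len(hits) == 1 and hits[0].span == (0, len(stw.sequence)):
            return stw
    raise RuntimeError(
        f"could not generate a clean stwintron in {max_retries} retries "
        f"(gc={spec.gc}); relax clean or adjust the spec"
    )


@dataclass(frozen=True)
class SyntheticGene:
    """A planted gene: exon context plus the annotated stwintron within it."""

    context: GeneContext
    stwintron: AnnotatedStwintron
    strand: str = "+"

    @property
    def sequence(self) -> str:
        return (
            self.context.upstream_exon
            + self.context.stwintron
            + self.context.downstream_exon
        )


def make_gene(
    spec: PlantSpec,
    seed=0,
    exon_len: int = 60,
    clean: bool = True,
    strand: str = "+",
) -> SyntheticGene:
    """A stwintron flanked by random exons of length ``exon_len``.

    The base immediately downstream is resampled away from G with the
    background distribution, so the [A2,3] alternative arises at the
    background G frequency.
    """
    rng = _rng(seed)
    stw = make_stwintron(spec, rng, clean=clean)
    upstream = random_background(exon_len, spec.gc, rng)
    downstream = random_background(exon_len, spec.gc, rng)
    ctx = GeneContext(
        upstream_exon=upstream,
        stwintron=stw.sequence,
        downstream_exon=downstream,
        internal_span=stw.internal_span,
        cds_offset_before=spec.phase,
        split_point=spec.model.donor_split,
        donor_universe=tuple(spec.model.external.donors),
    )
    return SyntheticGene(context=ctx, stwintron=stw, strand=strand)


@dataclass
class TruthSet:
    """Synthetic contigs plus the exact coordinates of every planted stwintron."""

    contigs: dict[str, str]
    truth: list[StwintronCandidate] = field(default_factory=list)
    seed: int | None = None

    def to_files(self, outdir: str | Path) -> dict[str, Path]:
        """Write genome.fa and truth.gff3; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fasta = outdir / "genome.fa"
        with fasta.open("w") as fh:
            for cid, seq in self.contigs.items():
                fh.write(f">{cid}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        gff = outdir / "truth.gff3"
        report = ScanReport(candidates=list(self.truth), mode="truth")
        write_candidates(report, gff, format="gff3")
        return {"fasta": fasta, "gff3": gff}


def plant(genome, genes, seed=0, contig_id: str = "contig_1") -> TruthSet:
    """Place synthetic genes at random non-overlapping positions.

    ``genome`` is a background string (or mapping id -> string; genes are
    planted into the first contig).  Each gene's full sequence replaces a
    background slice of equal length; minus-strand genes are inserted as
    their reverse complement.  Placements are uniform among positions that
    do not overlap previously placed genes.
    """
    rng = _rng(seed)
    if isinstance(genome, dict):
        contigs = dict(genome)
        target = next(iter(contigs))
    else:
        contigs = {contig_id: str(genome)}
        target = contig_id
    seq = list(contigs[target])
    occupied: list[tuple[int, int]] = []
    truth: list[StwintronCandidate] = []
    for gene in genes:
        if isinstance(gene, GeneContext):
            raise TypeError(
                "plant needs SyntheticGene objects (annotation carries the truth spans); "
                "use make_gene to build them"
            )
        gseq = gene.sequence
        if gene.strand == "-":
            gseq = reverse_complement(gseq)
        if len(gseq) > len(seq):
            raise ValueError("gene longer than the background contig")
        for _ in range(1000):
            start = int(rng.integers(0, len(seq) - len(gseq) + 1))
            span = (start, start + len(gseq))
            if all(span[1] <= s or span[0] >= e for s, e in occupied):
                break
        else:
            raise RuntimeError("could not place gene without overlap in 1000 tries")
        occupied.append(span)
        seq[span[0] : span[1]] = gseq
        up_len = len(gene.context.upstream_exon)
        stw_len = len(gene.context.stwintron)
        if gene.strand == "+":
            stw_start = span[0] + up_len
            stw_end = stw_start + stw_len
        else:
            down_len = len(gene.context.downstream_exon)
            stw_start = span[0] + down_len
            stw_end = stw_start + stw_len
        truth.append(
            StwintronCandidate(
                contig_id=target,
                strand=gene.strand,
                start=stw_start,
                end=stw_end,
                motif_spans=gene.stwintron.motif_spans,
                sequence=gene.stwintron.sequence,
                model_names=(gene.stwintron.spec.model.name,),
                stw_type=gene.stwintron.spec.model.stw_type,
            )
        )
    contigs[target] = "".join(seq)
    truth.sort(key=lambda c: (c.contig_id, c.start, c.strand))
    return TruthSet(contigs=contigs, truth=truth, seed=seed if isinstance(seed, int) else None)


@dataclass(frozen=True)
class SimRead:
    id: str
    sequence: str
    isoform: str
    orientation: str  # "fwd" | "rev"

    def to_fastq(self) -> str:
        return f"@{self.id} isoform={self.isoform}\n{self.sequence}\n+\n{'I' * len(self.sequence)}\n"


def simulate_reads(
    gene: GeneContext,
    mixture: dict[str, float],
    n: int,
    read_len: int = 100,
    seed=0,
) -> list[SimRead]:
    """Draw error-free reads from the gene's transcript isoforms.

    ``mixture`` maps isoform names ({"pre", "splinter", "mature",
    "one_step"}) to proportions summing to 1; read counts per isoform are
    multinomial.  Reads start uniformly along the isoform and are reported
    in either orientation with equal probability, labelled with their
    isoform of origin.
    """
    if isinstance(gene, SyntheticGene):
        gene = gene.context
    unknown = set(mixture) - set(_ISOFORMS)
    if unknown:
        raise ValueError(f"unknown isoforms {sorted(unknown)}; valid: {_ISOFORMS}")
    probs = [mixture.get(iso, 0.0) for iso in _ISOFORMS]
    if abs(sum(probs) - 1.0) > 1e-9:
        raise ValueError("mixture proportions must sum to 1")
    rng = _rng(seed)
    products = splice(gene)
    templates = {
        "pre": products.pre_mrna,
        "splinter": products.splinter,
        "mature": products.mature,
        "one_step": products.one_step,
    }
    if n == 0:
        return []
    counts = rng.multinomial(n, probs)
    reads: list[SimRead] = []
    idx = 0
    for iso, count in zip(_ISOFORMS, counts):
        template = templates[iso]
        if count and len(template) < read_len:
            raise ValueError(
                f"isoform {iso!r} ({len(template)} nt) shorter than read length {read_len}"
            )
        for _ in range(count):
            idx += 1
            start = int(rng.integers(0, len(template) - read_len + 1))
            frag = template[start : start + read_len]
            if rng.integers(2):
                frag = reverse_complement(frag)
                orient = "rev"
            else:
                orient = "fwd"
            reads.append(SimRead(id=f"read_{idx}", sequence=frag, isoform=iso, orientation=orient))
    return reads
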