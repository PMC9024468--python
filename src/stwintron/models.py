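"""Parametric stwintron search models.

A search model describes the five degenerate sequence motifs of a nested
intron (numbered 1-5 in scan order) together with the four spacer-length
ranges that separate them.  For a [D]-class stwintron whose internal intron
splits the external 5'-donor after position *n* (type [Dn,n+1]):

* motif 1 (5' hybrid): external donor positions 1..n + full internal donor;
* motif 2: internal branch-point (BP) element (consensus ``DYTRAY``);
* motif 3 (3' hybrid): internal 3'-acceptor (``HAG``) + external donor
  positions n+1..6;
* motif 4: external BP element;
* motif 5: external 3'-acceptor (``HAG``).

For an [A2,3] stwintron the internal intron splits the external acceptor
between its second and third base; the motif chain is external donor,
external BP, hybrid ``HA``+internal donor, internal BP, and internal
acceptor + the final ``G`` of the external acceptor.

All motifs are stored and matched on the DNA alphabet (T, not U); genomic
contigs are the expected subject sequences.
"""

from __future__ import annotations

import configparser
import io
import itertools
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

__all__ = [
    "IUPAC",
    "DONOR_SET_24",
    "SpliceElementSpec",
    "StwintronSearchModel",
    "MotifToken",
    "expand_iupac",
    "preset_model",
    "model_to_pattern",
    "load_model_config",
]

#: IUPAC degenerate nucleotide codes mapped to the concrete bases they admit.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: The 24 hexamer 5'-donor sequences used by the preset models.  They are
#: the subset of the 64 possible GTNNGN donors that each represent >0.6% of
#: genuine filamentous-fungal U2 intron donors; all start with GT and carry
#: G at position 5.
DONOR_SET_24: tuple[str, ...] = (
    "GTAAGT", "GTATGT", "GTGAGT", "GTACGT", "GTAAGC", "GTATGC",
    "GTAGGT", "GTAAGA", "GTGCGT", "GTACGC", "GTGAGC", "GTATGA",
    "GTAAGG", "GTTAGT", "GTCAGT", "GTGAGA", "GTGTGT", "GTTTGT",
    "GTACGA", "GTATGG", "GTTCGT", "GTGGGT", "GTAGGC", "GTACGG",
)

_STW_TYPES = ("D12", "D23", "D34", "D45", "D56", "A23")


def expand_iupac(motif: str) -> set[str]:
    """Expand a degenerate IUPAC motif into the set of concrete strings.

    >>> sorted(expand_iupac("HAG"))
    ['AAG', 'CAG', 'TAG']
    """
    try:
        choices = [sorted(IUPAC[c]) for c in motif.upper()]
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character {exc.args[0]!r} in motif {motif!r}") from None
    return {"".join(p) for p in itertools.product(*choices)}


def _check_iupac(motif: str, name: str, length: int) -> str:
    motif = motif.upper()
    if len(motif) != length:
        raise ValueError(f"{name} must be {length} nt long, got {motif!r}")
    bad = [c for c in motif if c not in IUPAC]
    if bad:
        raise ValueError(f"{name} contains non-IUPAC characters {bad} in {motif!r}")
    return motif


@dataclass(frozen=True)
class SpliceElementSpec:
    """Degenerate splice elements and spacer ranges for one constituent intron.

    Parameters
    ----------
    donors
        Concrete 6-mer 5'-donor sequences over {A,C,G,T}; order is
        preserved (the preset donor set is listed in genomic frequency
        order, and the rendered pattern follows it).
    bp_motif
        6-character IUPAC branch-point consensus (default ``DYTRAY``).
    acceptor_motif
        3-character IUPAC 3'-acceptor consensus (default ``HAG``).
    donor_bp_spacer, bp_acceptor_spacer
        Closed integer ranges (min, max), counting the nucleotides strictly
        between the two elements.
    """

    donors: tuple[str, ...]
    bp_motif: str = "DYTRAY"
    acceptor_motif: str = "HAG"
    donor_bp_spacer: tuple[int, int] = (25, 80)
    bp_acceptor_spacer: tuple[int, int] = (4, 20)

    def __post_init__(self) -> None:
        donors = tuple(dict.fromkeys(d.upper() for d in self.donors))
        if not donors:
            raise ValueError("donor set must not be empty")
        for d in donors:
            if len(d) != 6 or any(c not in "ACGT" for c in d):
                raise ValueError(f"donor {d!r} is not a 6-mer over ACGT")
        object.__setattr__(self, "donors", donors)
        object.__setattr__(self, "bp_motif", _check_iupac(self.bp_motif, "bp_motif", 6))
        object.__setattr__(
            self, "acceptor_motif", _check_iupac(self.acceptor_motif, "acceptor_motif", 3)
        )
        for label, (lo, hi) in (
            ("donor_bp_spacer", self.donor_bp_spacer),
            ("bp_acceptor_spacer", self.bp_acceptor_spacer),
        ):
            if lo < 0 or lo > hi:
                raise ValueError(f"{label} range ({lo},{hi}) must satisfy 0 <= min <= max")

    @property
    def min_intron_length(self) -> int:
        """Shortest canonical intron this element set admits (donor+spacers+BP+acceptor)."""
        return 6 + self.donor_bp_spacer[0] + 6 + self.bp_acceptor_spacer[0] + 3


class MotifToken:
    """One of the five scan motifs: equally long IUPAC alternatives."""

    __slots__ = ("name", "alternatives", "length")

    def __init__(self, name: str, alternatives: Iterable[str]):
        alts = tuple(dict.fromkeys(a.upper() for a in alternatives))
        if not alts:
            raise ValueError(f"motif {name} has no alternatives")
        lengths = {len(a) for a in alts}
        if len(lengths) != 1:
            raise ValueError(f"motif {name} alternatives differ in length: {lengths}")
        self.name = name
        self.alternatives = alts
        self.length = lengths.pop()

    def matches_at(self, seq: str, pos: int) -> bool:
        if pos < 0 or pos + self.length > len(seq):
            return False
        window = seq[pos : pos + self.length]
        return any(
            all(base in IUPAC[code] for base, code in zip(window, alt))
            for alt in self.alternatives
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"MotifToken({self.name}, {len(self.alternatives)} alt x {self.length} nt)"


@dataclass(frozen=True)
class StwintronSearchModel:
    """A pair of constituent-intron element specs plus the hybrid-motif rule.

    ``stw_type`` selects how the two hybrid motifs are assembled: ``"D12"``
    ... ``"D56"`` split the external donor after position 1..5; ``"A23"``
    splits the external acceptor between its penultimate and ultimate base.
    """

    stw_type: str
    internal: SpliceElementSpec
    external: SpliceElementSpec
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.stw_type not in _STW_TYPES:
            raise ValueError(
                f"unknown stwintron type {self.stw_type!r}; expected one of {_STW_TYPES}"
            )

    @property
    def donor_split(self) -> int:
        """For [D]-class models, number of external-donor nt 5' of the internal intron."""
        if self.stw_type.startswith("D"):
            return int(self.stw_type[1])
        raise AttributeError("donor_split is defined for [D]-class models only")

    def motifs(self) -> tuple[MotifToken, ...]:
        """The five motifs in scan (5'->3') order."""
        if self.stw_type.startswith("D"):
            n = self.donor_split
            ext_heads = tuple(dict.fromkeys(d[:n] for d in self.external.donors))
            ext_tails = tuple(dict.fromkeys(d[n:] for d in self.external.donors))
            return (
                MotifToken(
                    "hybrid1", (h + d for h in ext_heads for d in self.internal.donors)
                ),
                MotifToken("internal_bp", (self.internal.bp_motif,)),
                MotifToken(
                    "hybrid3", (self.internal.acceptor_motif + t for t in ext_tails)
                ),
                MotifToken("external_bp", (self.external.bp_motif,)),
                MotifToken("acceptor", (self.external.acceptor_motif,)),
            )
        # A23: external intron is mostly 5' of the internal one.
        acc = self.external.acceptor_motif
        return (
            MotifToken("external_donor", self.external.donors),
            MotifToken("external_bp", (self.external.bp_motif,)),
            MotifToken("hybrid_acc", (acc[:2] + d for d in self.internal.donors)),
            MotifToken("internal_bp", (self.internal.bp_motif,)),
            MotifToken("acceptor3", (self.internal.acceptor_motif + acc[2],)),
        )

    def spacer_ranges(self) -> tuple[tuple[int, int], ...]:
        """The four spacer ranges between consecutive motifs, in scan order."""
        if self.stw_type.startswith("D"):
            return (
                self.internal.donor_bp_spacer,
                self.internal.bp_acceptor_spacer,
                self.external.donor_bp_spacer,
                self.external.bp_acceptor_spacer,
            )
        return (
            self.external.donor_bp_spacer,
            self.external.bp_acceptor_spacer,
            self.internal.donor_bp_spacer,
            self.internal.bp_acceptor_spacer,
        )

    @property
    def min_length(self) -> int:
        """Shortest stwintron span the model can report."""
        return sum(m.length for m in self.motifs()) + sum(lo for lo, _ in self.spacer_ranges())

    @property
    def max_length(self) -> int:
        return sum(m.length for m in self.motifs()) + sum(hi for _, hi in self.spacer_ranges())


def preset_model(name: str) -> StwintronSearchModel:
    """The four published [D1,2] search models.

    Model A is the primary screen: 24-donor set for both constituent
    introns, BP consensus ``DYTRAY`` and acceptor ``HAG`` for both, spacer
    ranges 25-80/4-20 nt (internal) and 25-110/4-20 nt (external).  The
    secondary screens differ in a single variable each: Model B widens the
    internal donor-BP spacer to 81-110 nt, Model C moves the external
    donor-BP spacer to 111-200 nt, and Model D relaxes the external BP to
    the less canonical ``CCTRAY``.
    """
    key = name.strip().upper()
    base_internal = SpliceElementSpec(
        donors=DONOR_SET_24,
        bp_motif="DYTRAY",
        acceptor_motif="HAG",
        donor_bp_spacer=(25, 80),
        bp_acceptor_spacer=(4, 20),
    )
    base_external = replace(base_internal, donor_bp_spacer=(25, 110))
    if key == "A":
        return StwintronSearchModel("D12", base_internal, base_external, name="A")
    if key == "B":
        return StwintronSearchModel(
            "D12", replace(base_internal, donor_bp_spacer=(81, 110)), base_external, name="B"
        )
    if key == "C":
        return StwintronSearchModel(
            "D12", base_internal, replace(base_external, donor_bp_spacer=(111, 200)), name="C"
        )
    if key == "D":
        return StwintronSearchModel(
            "D12", base_internal, replace(base_external, bp_motif="CCTRAY"), name="D"
        )
    raise ValueError(f"unknown preset {name!r}; valid presets are A, B, C, D")


def _iupac_to_class(code: str) -> str:
    bases = sorted(IUPAC[code])
    return bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]"


def _iupac_pattern(motif: str) -> str:
    return "".join(_iupac_to_class(c) for c in motif)


def _alternation(options: Iterable[str], factor_prefix: bool) -> str:
    """Donor(-fragment) alternation; optionally factor a shared leading base."""
    opts = list(dict.fromkeys(options))
    prefix = ""
    if factor_prefix:
        while opts[0] and all(o[0] == opts[0][0] for o in opts):
            prefix += opts[0][0]
            opts = [o[1:] for o in opts]
    if not opts[0]:
        return prefix
    if len(opts) == 1:
        return prefix + opts[0]
    return prefix + "(" + "|".join(opts) + ")"


def model_to_pattern(model: StwintronSearchModel) -> str:
    """Render the model as a degenerate pattern string.

    The dialect matches the published Model A formula: the 5' hybrid is the
    literal external-donor head followed by the full internal-donor
    alternation (``G(GTAAGT|...)``), IUPAC elements become per-position
    character classes (``[AGT][CT]T[AG]A[CT]`` for ``DYTRAY``), spacers
    become ``.{lo,hi}`` bounded wildcard runs, and the 3' hybrid factors the
    donor-tail positions that are constant across the donor set
    (``[ACT]AGT(AAGT|...)``).  The pattern is equivalent to direct model
    execution by the scanner (which additionally refuses N anywhere in a
    candidate span).
    """
    internal, external = model.internal, model.external
    if model.stw_type.startswith("D"):
        n = model.donor_split
        heads = tuple(dict.fromkeys(d[:n] for d in external.donors))
        tails = tuple(dict.fromkeys(d[n:] for d in external.donors))
        motif_patterns = [
            _alternation(heads, factor_prefix=False)
            + _alternation(internal.donors, factor_prefix=False),
            _iupac_pattern(internal.bp_motif),
            _iupac_pattern(internal.acceptor_motif)
            + _alternation(tails, factor_prefix=True),
            _iupac_pattern(external.bp_motif),
            _iupac_pattern(external.acceptor_motif),
        ]
    else:  # A23
        acc = external.acceptor_motif
        motif_patterns = [
            _alternation(external.donors, factor_prefix=False),
            _iupac_pattern(external.bp_motif),
            _iupac_pattern(acc[:2]) + _alternation(internal.donors, factor_prefix=False),
            _iupac_pattern(internal.bp_motif),
            _iupac_pattern(internal.acceptor_motif) + _iupac_pattern(acc[2]),
        ]
    parts: list[str] = []
    for i, mp in enumerate(motif_patterns):
        parts.append(mp)
        if i < 4:
            lo, hi = model.spacer_ranges()[i]
            parts.append(f".{{{lo},{hi}}}" if lo != hi else f".{{{lo}}}")
    return "".join(parts)


def _parse_range(text: str, key: str) -> tuple[int, int]:
    for sep in ("-", ",", ".."):
        if sep in text:
            lo, hi = text.split(sep, 1)
            return int(lo), int(hi)
    raise ValueError(f"cannot parse spacer range {text!r} for {key} (use e.g. '25-80')")


def _element_from_section(sec: configparser.SectionProxy, prefix: str) -> SpliceElementSpec:
    def get(key: str, default: str | None = None) -> str:
        val = sec.get(f"{prefix}.{key}", default)
        if val is None:
            raise ValueError(f"missing key {prefix}.{key} in model config")
        return val

    donors = tuple(d for d in get("donors").replace(",", " ").split() if d)
    return SpliceElementSpec(
        donors=donors,
        bp_motif=get("bp", "DYTRAY"),
        acceptor_motif=get("acceptor", "HAG"),
        donor_bp_spacer=_parse_range(get("donor_bp"), f"{prefix}.donor_bp"),
        bp_acceptor_spacer=_parse_range(get("bp_acc"), f"{prefix}.bp_acc"),
    )


def load_model_config(source: str | Path) -> StwintronSearchModel:
    """Load a custom search model from an INI/flat key-value file.

    Recognised keys (in a ``[model]`` section, or bare): ``type``, ``name``,
    ``internal.donors`` (whitespace/comma separated hexamers),
    ``internal.bp``, ``internal.acceptor``, ``internal.donor_bp`` (e.g.
    ``25-80``), ``internal.bp_acc``, and the ``external.*`` equivalents.
    """
    path = Path(source)
    text = path.read_text()
    if not text.lstrip().startswith("["):
        text = "[model]\n" + text
    parser = configparser.ConfigParser()
    parser.read_file(io.StringIO(text))
    sec = parser[parser.sections()[0]]
    stw_type = sec.get("type", "D12").upper()
    return StwintronSearchModel(
        stw_type=stw_type,
        internal=_element_from_section(sec, "internal"),
        external=_element_from_section(sec, "external"),
        name=sec.get("name", path.stem),
    )
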