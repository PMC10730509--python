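"""Chimeric optoXR design: rule sets, stitching, and back-translation.

An optoXR grafts the G-protein-coupling surfaces of a target class-A GPCR
onto a light-sensitive rhodopsin backbone.  Two rule sets are provided:

``V1``
    The legacy design: all three intracellular loops (with a configurable
    number of proximal transmembrane residues on each flank) and the
    C-terminus come from the target; everything else stays backbone.

``V2``
    The optimized design: ICL1 is retained from the backbone (it contributes
    little to G-protein binding, and keeping it preserves structural
    integrity of the photoreceptor core), while ICL2, ICL3 and the
    C-terminus come from the target, with the C-terminal exchange point
    moved a configurable number of residues into TM7 to capture additional
    G-protein contact sites.

Both presets append the rhodopsin 1D4 epitope (``TETSQVAPA``) so chimeras
can be immunolabeled with anti-rhodopsin antibodies; the epitope is
configurable or can be disabled.

Every designed residue carries a provenance record (which input sequence and
which residue it came from, and which backbone segment it belongs to), so a
design can be audited, diffed against another rule set, and exported as a
GFF3 feature map.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
from Bio.Data import CodonTable as _BioCodonTable

from .align import GAP, AlignmentColumnMap
from .topology import (
    AMINO_ALPHABET,
    CANONICAL_SEGMENT_ORDER,
    ICL_SEGMENTS,
    ProteinSequence,
    TopologyAnnotation,
)

BACKBONE = "BACKBONE"
TARGET = "TARGET"
EPITOPE = "EPITOPE"

#: C-terminal rhodopsin residues recognized by the 1D4 antibody.
DEFAULT_EPITOPE = "TETSQVAPA"

DEFAULT_PROXIMAL_TM_OFFSET = 2
DEFAULT_V2_CTERM_CUT_SHIFT = 8


class DesignError(ValueError):
    """Raised when a rule set or chimera design is invalid."""


def _preset_sources(icl1: str) -> dict[str, str]:
    sources = {name: BACKBONE for name in CANONICAL_SEGMENT_ORDER}
    sources.update({"ICL1": icl1, "ICL2": TARGET, "ICL3": TARGET,
                    "CTERM": TARGET, "H8": TARGET})
    return sources


@dataclass(frozen=True)
class ChimeraRuleSet:
    """Declarative per-segment source assignments plus boundary offsets.

    ``proximal_tm_offset`` is the number of flanking TM residues taken from
    the target on each side of a swapped intracellular loop.
    ``cterm_cut_shift`` moves the C-terminal exchange point from the
    TM7/C-terminus boundary toward the TM7 interior by that many residues.
    H8, when annotated, is treated as part of the C-terminal group.
    """

    name: str
    source_by_segment: Mapping[str, str]
    proximal_tm_offset: int = DEFAULT_PROXIMAL_TM_OFFSET
    cterm_cut_shift: int = 0
    epitope: str = DEFAULT_EPITOPE

    def __post_init__(self) -> None:
        if self.proximal_tm_offset < 0 or self.cterm_cut_shift < 0:
            raise DesignError("offsets must be non-negative")
        for seg, src in self.source_by_segment.items():
            if seg not in CANONICAL_SEGMENT_ORDER:
                raise DesignError(f"unknown segment {seg!r} in rule set")
            if src not in (BACKBONE, TARGET):
                raise DesignError(f"invalid source {src!r} for segment {seg}")
        for ch in self.epitope:
            if ch not in AMINO_ALPHABET or ch == "X":
                raise DesignError(f"epitope contains invalid residue {ch!r}")

    def source_of(self, segment_name: str) -> str:
        try:
            return self.source_by_segment[segment_name]
        except KeyError:
            raise DesignError(
                f"rule set {self.name!r} assigns no source to segment {segment_name}"
            ) from None


def make_ruleset(
    version: str,
    *,
    source_by_segment: Optional[Mapping[str, str]] = None,
    proximal_tm_offset: Optional[int] = None,
    cterm_cut_shift: Optional[int] = None,
    epitope: Optional[str] = None,
    keep_icl1: bool = False,
) -> ChimeraRuleSet:
    """Build a validated V1, V2, or custom rule set.

    Numeric offsets and the epitope may be overridden for the presets;
    segment sources may only be set for ``custom``.  ``keep_icl1`` selects
    the two-loop V1 variant in which the backbone ICL1 is retained.
    """
    version_up = version.upper() if version.lower() != "custom" else "custom"
    if version_up == "V1":
        if source_by_segment is not None:
            raise DesignError("segment sources are fixed for the V1 preset")
        if cterm_cut_shift not in (None, 0):
            raise DesignError("V1 keeps the C-terminal cut at the TM7 boundary "
                              "(cterm_cut_shift must be 0)")
        rs = ChimeraRuleSet(
            name="V1",
            source_by_segment=_preset_sources(icl1=BACKBONE if keep_icl1 else TARGET),
            proximal_tm_offset=(
                DEFAULT_PROXIMAL_TM_OFFSET if proximal_tm_offset is None
                else proximal_tm_offset
            ),
            cterm_cut_shift=0,
        )
    elif version_up == "V2":
        if source_by_segment is not None:
            raise DesignError("segment sources are fixed for the V2 preset")
        shift = DEFAULT_V2_CTERM_CUT_SHIFT if cterm_cut_shift is None else cterm_cut_shift
        if shift <= 0:
            raise DesignError("V2 requires cterm_cut_shift > 0")
        rs = ChimeraRuleSet(
            name="V2",
            source_by_segment=_preset_sources(icl1=BACKBONE),
            proximal_tm_offset=(
                DEFAULT_PROXIMAL_TM_OFFSET if proximal_tm_offset is None
                else proximal_tm_offset
            ),
            cterm_cut_shift=shift,
        )
    elif version_up == "custom":
        if source_by_segment is None:
            raise DesignError("custom rule sets require a full source_by_segment map")
        rs = ChimeraRuleSet(
            name="custom",
            source_by_segment=dict(source_by_segment),
            proximal_tm_offset=(
                DEFAULT_PROXIMAL_TM_OFFSET if proximal_tm_offset is None
                else proximal_tm_offset
            ),
            cterm_cut_shift=0 if cterm_cut_shift is None else cterm_cut_shift,
        )
    else:
        raise DesignError(f"unknown ruleset version {version!r}")
    if epitope is not None:
        rs = replace(rs, epitope=epitope)
    return rs


@dataclass(frozen=True)
class ProvenanceRecord:
    """Origin of one chimera residue."""

    source: str  # BACKBONE | TARGET | EPITOPE
    source_sequence_id: str
    source_index: int  # 1-based in the source sequence
    segment_name: str


@dataclass(frozen=True)
class ProvenanceBlock:
    """A maximal run of chimera residues from one source segment."""

    start: int  # 1-based in the chimera
    end: int
    source: str
    source_sequence_id: str
    source_start: int
    source_end: int
    segment_name: str


@dataclass(frozen=True)
class ChimeraDesign:
    """A stitched chimera with a per-residue provenance map."""

    chimera: ProteinSequence
    provenance: tuple[ProvenanceRecord, ...]
    ruleset_name: str
    inputs: Mapping[str, str]
    # Source assignment per backbone residue (after offsets were applied);
    # used by diff_designs to compare rule sets on a common coordinate axis.
    backbone_source: tuple[str, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "provenance", tuple(self.provenance))
        if len(self.provenance) != len(self.chimera):
            raise DesignError(
                f"provenance has {len(self.provenance)} records for "
                f"{len(self.chimera)} residues"
            )

    def provenance_blocks(self) -> list[ProvenanceBlock]:
        blocks: list[ProvenanceBlock] = []
        records = self.provenance
        i = 0
        while i < len(records):
            j = i
            while (
                j + 1 < len(records)
                and records[j + 1].source == records[i].source
                and records[j + 1].segment_name == records[i].segment_name
                and records[j + 1].source_index == records[j].source_index + 1
            ):
                j += 1
            blocks.append(
                ProvenanceBlock(
                    start=i + 1,
                    end=j + 1,
                    source=records[i].source,
                    source_sequence_id=records[i].source_sequence_id,
                    source_start=records[i].source_index,
                    source_end=records[j].source_index,
                    segment_name=records[i].segment_name,
                )
            )
            i = j + 1
        return blocks


def _source_array(
    backbone_topology: TopologyAnnotation, ruleset: ChimeraRuleSet
) -> list[str]:
    """Per-backbone-residue source after applying loop flanks and C-term shift."""
    L = backbone_topology.length
    src = [BACKBONE] * (L + 1)  # 1-based; index 0 unused
    for seg in backbone_topology.segments:
        seg_src = ruleset.source_of(seg.name)
        for p in range(seg.start, seg.end + 1):
            src[p] = seg_src

    segments = backbone_topology.segments
    by_index = {seg.name: k for k, seg in enumerate(segments)}

    # Proximal TM residues flanking each swapped intracellular loop also come
    # from the target; the extension is clamped to the adjacent segment.
    off = ruleset.proximal_tm_offset
    if off > 0:
        for name in ICL_SEGMENTS:
            if name not in by_index or ruleset.source_of(name) != TARGET:
                continue
            k = by_index[name]
            if k > 0:
                prev = segments[k - 1]
                for p in range(max(prev.start, prev.end - off + 1), prev.end + 1):
                    src[p] = TARGET
            if k + 1 < len(segments):
                nxt = segments[k + 1]
                for p in range(nxt.start, min(nxt.end, nxt.start + off - 1) + 1):
                    src[p] = TARGET

    # C-terminal exchange point moved into the preceding TM helix.
    shift = ruleset.cterm_cut_shift
    if shift > 0 and "CTERM" in by_index and ruleset.source_of("CTERM") == TARGET:
        first_cterm = by_index.get("H8", by_index["CTERM"])
        if first_cterm > 0:
            prev = segments[first_cterm - 1]
            for p in range(max(prev.start, prev.end - shift + 1), prev.end + 1):
                src[p] = TARGET
    return src[1:]


def design_chimera(
    backbone: ProteinSequence,
    backbone_topology: TopologyAnnotation,
    target: ProteinSequence,
    colmap: AlignmentColumnMap,
    ruleset: ChimeraRuleSet,
) -> ChimeraDesign:
    """Stitch a chimera from backbone and target following a rule set.

    The backbone topology is walked N-to-C.  Contiguous runs of residues
    assigned to the backbone are copied verbatim; runs assigned to the target
    are replaced by the homologous target region, located by projecting the
    run boundaries through the alignment (boundaries falling in alignment
    gaps shift toward the run interior).  The configured epitope, if any, is
    appended last.
    """
    backbone_topology.validate_against(backbone)
    if colmap.backbone_length != len(backbone) or colmap.target_length != len(target):
        raise DesignError("alignment does not cover the given backbone/target pair")

    src = _source_array(backbone_topology, ruleset)
    L = len(src)

    # Column bookkeeping: column index per backbone residue, plus the nearest
    # non-gap target index at-or-after / at-or-before each column.
    n_cols = len(colmap.columns)
    col_of_backbone = [0] * (L + 1)
    for k, (b, _) in enumerate(colmap.columns):
        if b is not GAP:
            col_of_backbone[b] = k
    next_target = [None] * n_cols
    prev_target = [None] * n_cols
    running = None
    for k in range(n_cols - 1, -1, -1):
        t = colmap.columns[k][1]
        if t is not GAP:
            running = t
        next_target[k] = running
    running = None
    for k in range(n_cols):
        t = colmap.columns[k][1]
        if t is not GAP:
            running = t
        prev_target[k] = running

    # Backbone segment label for each target residue (via the alignment);
    # inserted target residues inherit the preceding backbone residue's
    # segment (or the first segment at the very start).
    target_segment = [None] * (len(target) + 1)
    last_seg = backbone_topology.segments[0].name
    for b, t in colmap.columns:
        if b is not GAP:
            last_seg = backbone_topology.segment_of(b).name
        if t is not GAP:
            target_segment[t] = last_seg

    residues: list[str] = []
    provenance: list[ProvenanceRecord] = []

    pos = 1
    while pos <= L:
        run_src = src[pos - 1]
        end = pos
        while end + 1 <= L and src[end] == run_src:
            end += 1
        if run_src == BACKBONE:
            for p in range(pos, end + 1):
                residues.append(backbone.residues[p - 1])
                provenance.append(
                    ProvenanceRecord(
                        source=BACKBONE,
                        source_sequence_id=backbone.id,
                        source_index=p,
                        segment_name=backbone_topology.segment_of(p).name,
                    )
                )
        else:
            ts = next_target[col_of_backbone[pos]]
            te = prev_target[col_of_backbone[end]]
            if ts is None or te is None or ts > te:
                seg_name = backbone_topology.segment_of(pos).name
                raise DesignError(
                    f"exchanged region at segment {seg_name} collapses to zero "
                    "length on the target"
                )
            donor = target.residues[ts - 1 : te]
            if "X" in donor:
                seg_name = backbone_topology.segment_of(pos).name
                raise DesignError(
                    f"target region {ts}..{te} swapped at segment {seg_name} "
                    "contains unknown residue 'X'"
                )
            for t in range(ts, te + 1):
                residues.append(target.residues[t - 1])
                provenance.append(
                    ProvenanceRecord(
                        source=TARGET,
                        source_sequence_id=target.id,
                        source_index=t,
                        segment_name=target_segment[t],
                    )
                )
        pos = end + 1

    for k, ch in enumerate(ruleset.epitope, start=1):
        residues.append(ch)
        provenance.append(
            ProvenanceRecord(
                source=EPITOPE,
                source_sequence_id="1D4",
                source_index=k,
                segment_name="EPITOPE",
            )
        )

    chimera = ProteinSequence(
        id=f"opto_{target.id}_{ruleset.name}",
        residues="".join(residues),
        description=f"chimera of {backbone.id} x {target.id} ({ruleset.name})",
    )
    design = ChimeraDesign(
        chimera=chimera,
        provenance=tuple(provenance),
        ruleset_name=ruleset.name,
        inputs={
            "backbone_id": backbone.id,
            "backbone_checksum": backbone.checksum(),
            "target_id": target.id,
            "target_checksum": target.checksum(),
            "alignment_checksum": colmap.checksum(),
        },
        backbone_source=tuple(src),
    )
    _check_provenance(design, backbone, target)
    return design


def _check_provenance(
    design: ChimeraDesign, backbone: ProteinSequence, target: ProteinSequence
) -> None:
    """Verify that provenance-addressed residues reproduce the chimera."""
    epitope = "".join(
        design.chimera.residues[i]
        for i, rec in enumerate(design.provenance)
        if rec.source == EPITOPE
    )
    lookup = {BACKBONE: backbone.residues, TARGET: target.residues, EPITOPE: epitope}
    rebuilt = "".join(
        lookup[rec.source][rec.source_index - 1] for rec in design.provenance
    )
    if rebuilt != design.chimera.residues:
        raise DesignError("provenance does not reproduce the chimera sequence")


@dataclass(frozen=True)
class DesignDifference:
    """A backbone residue range whose source differs between two designs."""

    start: int
    end: int
    segments: tuple[str, ...]
    source_a: str
    source_b: str


def diff_designs(a: ChimeraDesign, b: ChimeraDesign,
                 backbone_topology: TopologyAnnotation) -> list[DesignDifference]:
    """Compare two designs built from the same backbone/target pair.

    Returns the backbone residue ranges whose source assignment differs,
    labeled by the backbone segments they touch.  Designs from different
    inputs are not comparable and raise :class:`DesignError`.
    """
    for key in ("backbone_checksum", "target_checksum"):
        if a.inputs[key] != b.inputs[key]:
            raise DesignError(
                f"designs built from different inputs ({key} mismatch)"
            )
    if len(a.backbone_source) != len(b.backbone_source):
        raise DesignError("designs carry incompatible backbone source maps")
    diffs: list[DesignDifference] = []
    L = len(a.backbone_source)
    pos = 1
    while pos <= L:
        if a.backbone_source[pos - 1] == b.backbone_source[pos - 1]:
            pos += 1
            continue
        end = pos
        while (
            end + 1 <= L
            and a.backbone_source[end] != b.backbone_source[end]
            and a.backbone_source[end] == a.backbone_source[pos - 1]
            and b.backbone_source[end] == b.backbone_source[pos - 1]
        ):
            end += 1
        segments = []
        for p in range(pos, end + 1):
            name = backbone_topology.segment_of(p).name
            if not segments or segments[-1] != name:
                segments.append(name)
        diffs.append(
            DesignDifference(
                start=pos,
                end=end,
                segments=tuple(segments),
                source_a=a.backbone_source[pos - 1],
                source_b=b.backbone_source[pos - 1],
            )
        )
        pos = end + 1
    return diffs


# ---------------------------------------------------------------------------
# Codon-optimized back-translation


_STANDARD_TABLE = _BioCodonTable.unambiguous_dna_by_id[1]


def _codon_to_aa(codon: str) -> str:
    if codon in _STANDARD_TABLE.stop_codons:
        return "*"
    return _STANDARD_TABLE.forward_table[codon]


@dataclass(frozen=True)
class CodonUsageTable:
    """Relative synonymous codon frequencies per amino acid.

    Frequencies are normalized to sum to 1 within each amino acid, and every
    codon is checked against the standard genetic code.
    """

    name: str
    frequencies: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        for aa, codons in self.frequencies.items():
            if not codons:
                raise DesignError(f"amino acid {aa!r} has no codons")
            total = sum(codons.values())
            if abs(total - 1.0) > 1e-9:
                raise DesignError(
                    f"codon frequencies for {aa!r} sum to {total}, not 1"
                )
            for codon in codons:
                if _codon_to_aa(codon) != aa:
                    raise DesignError(
                        f"codon {codon} does not translate to {aa!r}"
                    )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CodonUsageTable":
        """Read ``aa<TAB>codon<TAB>freq`` rows; frequencies are renormalized."""
        raw: dict[str, dict[str, float]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if fields[0].lower() in ("aa", "amino_acid"):
                    continue
                if len(fields) != 3:
                    raise DesignError(f"{path}:{lineno}: expected aa<TAB>codon<TAB>freq")
                aa, codon, freq = fields[0].upper(), fields[1].upper(), float(fields[2])
                raw.setdefault(aa, {})[codon.replace("U", "T")] = freq
        normalized = {
            aa: {c: f / sum(codons.values()) for c, f in codons.items()}
            for aa, codons in raw.items()
        }
        return cls(name=Path(path).stem, frequencies=normalized)

    @classmethod
    def default(cls) -> "CodonUsageTable":
        """The shipped table of approximate human codon usage fractions."""
        from importlib.resources import files

        path = files("optoxr") / "data" / "codon_usage_human.tsv"
        return cls.from_tsv(str(path))

    def codons_for(self, aa: str) -> dict[str, float]:
        try:
            return dict(self.frequencies[aa])
        except KeyError:
            raise DesignError(f"amino acid {aa!r} absent from codon table") from None


def back_translate(
    protein: ProteinSequence,
    table: Optional[CodonUsageTable] = None,
    mode: str = "most_frequent",
    seed: Optional[int] = None,
    append_stop: bool = False,
) -> str:
    """Back-translate a protein to DNA using a codon usage table.

    ``most_frequent`` always picks each amino acid's most used codon (ties
    broken alphabetically, so the output is fully deterministic);
    ``weighted`` samples codons proportionally to usage and requires a seed.
    Translating the output under the standard genetic code reproduces the
    protein exactly.
    """
    if table is None:
        table = CodonUsageTable.default()
    if mode not in ("most_frequent", "weighted"):
        raise DesignError(f"unknown back-translation mode {mode!r}")
    if mode == "weighted":
        if seed is None:
            raise DesignError("weighted mode requires a seed")
        rng = np.random.default_rng(seed)
    codons: list[str] = []
    targets = protein.residues + ("*" if append_stop else "")
    for aa in targets:
        options = table.codons_for(aa)
        if mode == "most_frequent":
            codons.append(max(sorted(options), key=lambda c: options[c]))
        else:
            names = sorted(options)
            weights = np.array([options[c] for c in names])
            codons.append(names[rng.choice(len(names), p=weights / weights.sum())])
    return "".join(codons)


def translate(dna: str) -> str:
    """Translate DNA under the standard genetic code (stops become ``*``)."""
    if len(dna) % 3 != 0:
        raise DesignError("DNA length is not a multiple of 3")
    return "".join(_codon_to_aa(dna[i : i + 3]) for i in range(0, len(dna), 3))


def design_from_files(
    backbone: ProteinSequence,
    target: ProteinSequence,
    backbone_topology: TopologyAnnotation,
    ruleset: ChimeraRuleSet,
    colmap: Optional[AlignmentColumnMap] = None,
    matrix=None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> ChimeraDesign:
    """Convenience wrapper: align (if needed) and design in one call."""
    from .align import global_align

    if colmap is None:
        colmap = global_align(backbone, target, matrix=matrix,
                              gap_open=gap_open, gap_extend=gap_extend)
    return design_chimera(backbone, backbone_topology, target, colmap, ruleset)
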