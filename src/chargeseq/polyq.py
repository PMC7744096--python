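"""Polyglutamine tract detection and -1 frameshift reporter logic.

Polyglutamine (polyQ) tracts — uninterrupted runs of >= 10 glutamine
residues — are encoded by CAG/CAA repeats.  When charged tRNA-Gln becomes
limiting, ribosomes stalled on a (CAG)n tract can slip one nucleotide
backward into the (GCA)n alanine frame.  The reporter constructs modeled
here turn that slip into a fluorescence readout: an insert carrying the
tract (a huntingtin-exon-1-like fragment) or a tract-free luciferase-like
fragment of equal length is fused through a GGGGS-GGGGS linker to an
ATG-less marker ORF (a GFP stand-in); a single-nucleotide deletion between
the tract and the linker makes the marker reachable only through a -1
frameshift.

The true HTT exon 1, GFP and Renilla luciferase sequences are not bundled;
the constructs use synthetic stand-ins generated deterministically with
the structural features that carry the frame logic (codon tract, linker,
deletion placement, stop-free -1 insert for the luciferase-like control).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
STOP_CODONS = {"TAA", "TAG", "TGA"}

# codon choices per amino acid used by the deterministic stand-in generator
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["CTT", "CTC", "CTA", "CTG", "TTA", "TTG"],
    "M": ["ATG"], "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"], "W": ["TGG"], "Y": ["TAT", "TAC"],
}


class PolyQError(ValueError):
    pass


@dataclass(frozen=True)
class PolyQTract:
    protein_id: str
    start: int  # 1-based residue position
    length: int


def scan_polyq(
    sequence: str, min_len: int = 10, protein_id: str = "protein"
) -> list[PolyQTract]:
    """All maximal glutamine runs of length >= ``min_len``, by position.

    X is tolerated and breaks tracts; any other letter outside the
    20-residue alphabet is an error.  Starts are 1-based.
    """
    seq = sequence.upper()
    illegal = set(seq) - AA_ALPHABET - {"X"}
    if illegal:
        raise PolyQError(f"{protein_id}: illegal residue(s) {sorted(illegal)}")
    tracts = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == "Q":
            j = i
            while j < n and seq[j] == "Q":
                j += 1
            if j - i >= min_len:
                tracts.append(PolyQTract(protein_id, i + 1, j - i))
            i = j
        else:
            i += 1
    return tracts


def polyq_census(
    fasta: str | os.PathLike, min_len: int = 10
) -> tuple[pd.DataFrame, dict]:
    """Scan a protein FASTA for polyQ tracts and tally glutamine content.

    Returns a per-tract table (protein_id, start, length) and a summary
    with the number of proteins scanned, the number carrying at least one
    tract, and the overall glutamine residue fraction (None for an empty
    set).  Duplicate identifiers are scanned with a warning.
    """
    if isinstance(fasta, str) and fasta.strip() == "":
        handle = StringIO("")
    elif isinstance(fasta, str) and fasta.lstrip().startswith(">"):
        handle = StringIO(fasta)
    else:
        import gzip

        handle = (
            gzip.open(fasta, "rt") if str(fasta).endswith(".gz") else open(fasta)
        )
    rows = []
    n_proteins = 0
    n_with_tract = 0
    total_q = 0
    total_res = 0
    seen: set[str] = set()
    with handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in seen:
                logger.warning("duplicate protein identifier %s; scanning both", record.id)
            seen.add(record.id)
            seq = str(record.seq).upper().rstrip("*")
            n_proteins += 1
            total_res += len(seq)
            total_q += seq.count("Q")
            tracts = scan_polyq(seq, min_len, protein_id=record.id)
            if tracts:
                n_with_tract += 1
            rows.extend(
                {"protein_id": t.protein_id, "start": t.start, "length": t.length}
                for t in tracts
            )
    summary = {
        "n_proteins": n_proteins,
        "n_with_tract": n_with_tract,
        "glutamine_fraction": (total_q / total_res) if total_res else None,
        "min_tract_len": min_len,
    }
    return pd.DataFrame(rows, columns=["protein_id", "start", "length"]), summary


# ---------------------------------------------------------------------------
# Reporter constructs
# ---------------------------------------------------------------------------

POLYQ_GFP = "polyq_gfp"
POLYQ_MINUS1_GFP = "polyq_minus1_gfp"
LUC_MINUS1_GFP = "luc_minus1_gfp"

LINKER_PEPTIDE = "GGGGSGGGGS"

# Peptides for the deterministic stand-ins.  The insert flanks echo the
# composition of HTT exon 1 (N-terminal peptide, then the proline-rich
# region after the tract); the marker ends in the recognizable GFP
# C-terminal signature DELYK.
_HTT_NTERM = "ATLEKLMRAFESLKSF"
_HTT_CTERM = "PPPQLPQPPPQAQPLLPQPQ"
_MARKER_CORE = (
    "SKGEELFTGVVPILVELDGDVNGHKFSVSGEGEGDATYGKLTLKFICTTGKLPVPWPTLVTTF"
    "SYGVQCFSRYPDHMKQHDFFKSAMPEGYVQERTIFFKDDGNYKTRAEVKFEGDTLVNRIELKG"
)
_MARKER_SIGNATURE = "DELYK"
_LUC_NTERM = "ASKVYDPEQRKRMLTGPQWWARCKQMRVLDSFINYYDSEKHAENAVIFLHGNAASSYLWRHVVPHIEPVARCIIPDLIGMG"


@dataclass(frozen=True)
class Feature:
    name: str
    start: int  # 0-based, inclusive
    end: int  # 0-based, exclusive


@dataclass(frozen=True)
class ReporterConstruct:
    name: str
    coding_sequence: str
    features: tuple[Feature, ...]
    polyq_codons: int

    def feature(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise PolyQError(f"{self.name}: no feature {name!r}")


@dataclass(frozen=True)
class FrameAnalysis:
    frames_yielding_marker: frozenset[int]
    tract_peptides: dict[int, str]
    first_stop: dict[int, int | None]  # 0-based nt position of stop codon or None


def _codon_stream(peptide: str, rng: np.random.Generator) -> list[str]:
    return [
        _CODONS[aa][int(rng.integers(0, len(_CODONS[aa])))] for aa in peptide
    ]


def _encode(
    peptide: str,
    rng: np.random.Generator,
    *,
    prev_tail: str,
    forbid_minus1_stops: bool,
) -> str:
    """Choose codons for ``peptide``; optionally keep the -1 frame stop-free.

    The -1 reading frame of a codon string is scanned as the codons formed
    one nucleotide to the left; each new codon is chosen so that no stop
    codon appears there, using ``prev_tail`` (the last two nt upstream) for
    the junction codons.
    """
    if not forbid_minus1_stops:
        return "".join(_codon_stream(peptide, rng))

    def clean(tail: str, codon: str) -> bool:
        window = tail[-2:] + codon
        return not any(
            window[i:i + 3] in STOP_CODONS for i in range(len(window) - 2)
        )

    # depth-first search over rng-shuffled synonymous codons; single-codon
    # residues (M, W) create narrow corridors that greedy choice can miss
    shuffled: list[list[str]] = []
    for aa in peptide:
        options = list(_CODONS[aa])
        rng.shuffle(options)
        shuffled.append(options)
    out: list[str] = []
    cursor = [0] * len(peptide)
    i = 0
    while i < len(peptide):
        tail = out[-1] if out else prev_tail
        while cursor[i] < len(shuffled[i]) and not clean(tail, shuffled[i][cursor[i]]):
            cursor[i] += 1
        if cursor[i] == len(shuffled[i]):
            cursor[i] = 0
            if not out:
                raise PolyQError(
                    f"cannot encode {peptide!r} without a -1 frame stop"
                )
            out.pop()
            i -= 1
            cursor[i] += 1
            continue
        out.append(shuffled[i][cursor[i]])
        i += 1
    return "".join(out)


def _has_stop(seq: str, offset: int) -> bool:
    return any(
        seq[i:i + 3] in STOP_CODONS for i in range(offset, len(seq) - 2, 3)
    )


def build_reporter(kind: str, polyq_codons: int = 36, seed: int = 2020) -> ReporterConstruct:
    """Assemble a reporter coding sequence with a feature map.

    ``polyq_gfp``: ATG + HTT-exon-1-like flank + (CAG)n + proline-rich
    flank + GGGGSGGGGS linker + ATG-less marker ORF + stop, all in frame 0.
    ``polyq_minus1_gfp``: the same with one nucleotide deleted between the
    tract-bearing insert and the linker, so the marker is reached only via
    a -1 shift within the tract.  ``luc_minus1_gfp``: the insert replaced
    by a tract-free luciferase-like fragment of equal length whose -1
    frame is engineered stop-free, with the same deletion.
    """
    if polyq_codons < 1:
        raise PolyQError("polyq_codons must be >= 1")
    if kind not in (POLYQ_GFP, POLYQ_MINUS1_GFP, LUC_MINUS1_GFP):
        raise PolyQError(f"unknown reporter kind {kind!r}")
    rng = np.random.default_rng(seed)

    if kind == LUC_MINUS1_GFP:
        # tract-free insert of the same length as flank+tract+flank,
        # stop-free in the -1 frame so a slip anywhere can reach the marker
        insert_codons = len(_HTT_NTERM) + polyq_codons + len(_HTT_CTERM)
        peptide = (_LUC_NTERM * ((insert_codons // len(_LUC_NTERM)) + 1))[:insert_codons]
        insert = _encode(peptide, rng, prev_tail="ATG", forbid_minus1_stops=True)
        tract_start = 3  # the whole insert doubles as the slip region
        tract_end = 3 + len(insert)
        insert_name = "luciferase_like_insert"
    else:
        nterm = _encode(_HTT_NTERM, rng, prev_tail="ATG", forbid_minus1_stops=True)
        tract = "CAG" * polyq_codons
        cterm = _encode(
            _HTT_CTERM, rng, prev_tail=tract[-3:], forbid_minus1_stops=True
        )
        insert = nterm + tract + cterm
        tract_start = 3 + len(nterm)
        tract_end = tract_start + len(tract)
        insert_name = "htt_exon1_like_insert"

    # the -1 reading of the linker+marker must contain a stop so that a
    # deletion-less construct cannot express the marker through a slip;
    # GGA GGC ... GGT followed downstream guarantees none here, so place a
    # dedicated -1 stop inside the marker by appending LK (CTT AAA -> -1
    # junction xCT TAA) right after the signature-free core start.
    linker = _encode(LINKER_PEPTIDE, rng, prev_tail="NNN", forbid_minus1_stops=False)
    marker_peptide = _MARKER_CORE + _MARKER_SIGNATURE
    marker = _codon_stream(marker_peptide, rng)
    marker[10] = "CTT"
    marker[11] = "AAA"  # -1 frame: ..T TAA -> stop inside the marker
    marker[13] = "GTA"
    marker[14] = "AAA"  # +1 frame: .TA A.. -> TAA stop inside the marker
    marker_seq = "".join(marker)
    if _has_stop(marker_seq, 0):  # keep frame 0 clean regardless of the draw
        raise PolyQError("marker stand-in drew a frame-0 stop")  # pragma: no cover

    deletion = kind in (POLYQ_MINUS1_GFP, LUC_MINUS1_GFP)
    pieces = ["ATG", insert]
    features = [Feature("start_codon", 0, 3)]
    if kind == LUC_MINUS1_GFP:
        features.append(Feature("slip_region", tract_start, tract_end))
    else:
        features.extend(
            [
                Feature(f"{insert_name}_5p", 3, tract_start),
                Feature("polyq_tract", tract_start, tract_end),
                Feature(f"{insert_name}_3p", tract_end, 3 + len(insert)),
            ]
        )
    pos = 3 + len(insert)
    if deletion:
        features.append(Feature("deletion_site", pos - 1, pos - 1))
    pieces.append(linker)
    features.append(Feature("linker", pos, pos + len(linker)))
    pos += len(linker)
    pieces.append(marker_seq)
    features.append(Feature("marker_orf", pos, pos + len(marker_seq)))
    pos += len(marker_seq)
    pieces.append("TAA")
    features.append(Feature("stop_codon", pos, pos + 3))

    cds = "".join(pieces)
    if deletion:
        # remove the last nucleotide of the insert: a single base deletion
        # downstream of the poly-CAG tract but upstream of the linker, so a
        # -1 slip re-aligns the ribosome with the linker/marker frame
        del_at = 3 + len(insert) - 1
        cds = cds[:del_at] + cds[del_at + 1:]
        features = [
            Feature(f.name, f.start - (1 if f.start > del_at else 0),
                    f.end - (1 if f.end > del_at else 0))
            for f in features
        ]
    return ReporterConstruct(kind, cds, tuple(features), polyq_codons)


def _translate_with_shift(
    cds: str, slip_at: int, shift: int
) -> tuple[str, int | None, list[tuple[int, int]]]:
    """Translate from ATG applying ``shift`` at nt position ``slip_at``.

    Returns (peptide, first stop nt position or None, list of (nt_pos,
    codon index) covered).  A -1 shift re-reads one nucleotide; +1 skips
    one.  Translation stops at the first stop codon.
    """
    peptide = []
    covered = []
    pos = 0
    shifted = False
    while pos + 3 <= len(cds):
        if not shifted and pos >= slip_at:
            pos += shift
            shifted = True
            if pos < 0 or pos + 3 > len(cds):
                break
        codon = cds[pos:pos + 3]
        if codon in STOP_CODONS:
            return "".join(peptide), pos, covered
        peptide.append(str(Seq(codon).translate()))
        covered.append((pos, len(peptide) - 1))
        pos += 3
    return "".join(peptide), None, covered


def analyze_reading_frames(construct: ReporterConstruct) -> FrameAnalysis:
    """Which reading outcomes (no shift, -1, +1 within the tract) express the marker.

    A frame yields the marker iff translation from the start codon, with
    the shift applied at the 5' boundary of the tract (slip) region,
    reaches the end of the marker ORF without encountering a stop codon.
    The peptide read across the tract region is reported per frame: polyQ
    in frame 0 and polyA in the -1 frame for a (CAG)n tract.
    """
    try:
        tract = construct.feature("polyq_tract")
    except PolyQError:
        tract = construct.feature("slip_region")
    try:
        marker = construct.feature("marker_orf")
    except PolyQError:
        raise PolyQError(f"{construct.name}: construct has no marker feature")

    cds = construct.coding_sequence
    frames = {}
    tract_peptides = {}
    first_stop = {}
    for shift in (0, -1, +1):
        slip_at = tract.start if shift else len(cds) + 3
        peptide, stop_pos, covered = _translate_with_shift(cds, slip_at, shift)
        reached = stop_pos is None or stop_pos >= marker.end
        if stop_pos is None:
            # ran off the end without a stop; require the marker was covered
            reached = covered and covered[-1][0] + 3 >= marker.end
        frames[shift] = bool(reached)
        first_stop[shift] = stop_pos
        tract_aa = [
            i for pos, i in covered if tract.start <= pos and pos + 3 <= tract.end
        ]
        tract_peptides[shift] = (
            peptide[tract_aa[0]:tract_aa[-1] + 1] if tract_aa else ""
        )
    return FrameAnalysis(
        frames_yielding_marker=frozenset(s for s, ok in frames.items() if ok),
        tract_peptides=tract_peptides,
        first_stop=first_stop,
    )


def write_construct(construct: ReporterConstruct, out_dir: str | os.PathLike) -> None:
    """Write construct FASTA plus a GFF-like feature table (1-based, inclusive)."""
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, f"{construct.name}.fasta"), "w") as fh:
        fh.write(f">{construct.name} synthetic reporter stand-in\n")
        fh.write(construct.coding_sequence + "\n")
    with open(os.path.join(out_dir, f"{construct.name}.features.tsv"), "w") as fh:
        fh.write("name\tstart\tend\n")
        for f in construct.features:
            fh.write(f"{f.name}\t{f.start + 1}\t{max(f.end, f.start + 1)}\n")
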