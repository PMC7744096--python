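"""tRNA gene reference handling.

Parses tRNA gene sets from FASTA with GtRNAdb-style headers
(``..._tRNA-<AA>-<Anticodon>-<n>-<m>``), deduplicates sequences, appends
the 3' CCA that is added post-transcriptionally to every mature tRNA, and
groups genes into isodecoders (tRNAs sharing an anticodon).  The resulting
index is the unit against which charging libraries are aligned and
quantified.  A single foreign spike-in tRNA (the yeast tRNA-Phe role) is
attached to the index for normalization and must be distinguishable from
every cellular sequence at more than the aligner's mismatch allowance.
"""

from __future__ import annotations

import gzip
import hashlib
import logging
import os
import re
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable

from Bio import SeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Amino-acid classes that appear in GtRNAdb headers.  "iMet" (initiator
# methionine) and "SeC" (selenocysteine) are kept as their own classes so
# iMet-CAT and Met-CAT form distinct isodecoder groups.
_AA_CODES = {
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
    "iMet", "SeC", "Sup",
}

_HEADER_RE = re.compile(r"tRNA-([A-Za-z]{3,4})-([A-Za-z]{3})")

MIN_TRNA_LEN = 60
MAX_TRNA_LEN = 120


class ReferenceError(ValueError):
    """Raised for malformed tRNA gene inputs or inconsistent references."""


@dataclass(frozen=True)
class TrnaGene:
    """One tRNA gene: genomic sequence (5'->3', no CCA assumed) plus identity."""

    gene_id: str
    amino_acid: str
    anticodon: str
    sequence: str
    is_spike_in: bool = False

    def __post_init__(self) -> None:
        if len(self.anticodon) != 3 or set(self.anticodon) - set("ACGT"):
            raise ReferenceError(
                f"{self.gene_id}: anticodon {self.anticodon!r} must be a 3-mer over ACGT"
            )
        if set(self.sequence) - set("ACGT"):
            bad = sorted(set(self.sequence) - set("ACGT"))
            raise ReferenceError(
                f"{self.gene_id}: sequence contains non-ACGT characters {bad}"
            )
        if not (MIN_TRNA_LEN <= len(self.sequence) <= MAX_TRNA_LEN):
            raise ReferenceError(
                f"{self.gene_id}: sequence length {len(self.sequence)} outside "
                f"[{MIN_TRNA_LEN}, {MAX_TRNA_LEN}]"
            )

    @property
    def isodecoder_key(self) -> str:
        return f"{self.amino_acid}-{self.anticodon}"


@dataclass(frozen=True)
class IsodecoderGroup:
    """Genes sharing one amino acid + anticodon, with their mature sequences."""

    key: str
    gene_ids: frozenset[str]
    unique_sequences: frozenset[str]


@dataclass
class ChargeRefIndex:
    """Deduplicated, CCA-appended, isodecoder-grouped tRNA reference.

    ``mature_sequences`` maps each unique mature (CCA-ended) sequence to the
    set of gene ids sharing it; ``isodecoders`` is keyed by ``AA-anticodon``;
    ``spike_in`` holds exactly one gene flagged as the spike-in standard.
    """

    genes: dict[str, TrnaGene]
    mature_sequences: dict[str, frozenset[str]]
    isodecoders: dict[str, IsodecoderGroup]
    spike_in: TrnaGene
    spike_mature: str
    gene_to_mature: dict[str, str] = field(default_factory=dict)

    def isodecoder_of(self, gene_id: str) -> str:
        if gene_id == self.spike_in.gene_id:
            raise KeyError(f"{gene_id} is the spike-in, not a cellular gene")
        return self.genes[gene_id].isodecoder_key


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def anticodon_to_codon(anticodon: str) -> str:
    """Codon read 5'->3' that an anticodon pairs with (strict Watson-Crick).

    Wobble decoding is deliberately not modeled: each anticodon maps to the
    single codon it is antiparallel-complementary to, e.g. CTG -> CAG and
    TTG -> CAA for the two glutamine isodecoders.
    """
    if len(anticodon) != 3 or set(anticodon) - set("ACGT"):
        raise ReferenceError(f"anticodon {anticodon!r} must be a 3-mer over ACGT")
    return reverse_complement(anticodon)


def _open_maybe_gzip(path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def parse_trna_fasta(fasta: str | os.PathLike, *, is_spike_in: bool = False) -> list[TrnaGene]:
    """Parse tRNA genes from FASTA text or a (optionally gzipped) file path.

    Headers must carry a ``tRNA-<AA>-<Anticodon>`` token.  U is silently
    converted to T; any other non-ACGT character is an error.  Records with
    an undetermined (NNN) anticodon or flagged as pseudogenes are dropped
    with a warning; records whose headers mark introns are rejected because
    intron excision is out of scope.
    """
    if isinstance(fasta, str) and fasta.strip() == "":
        return []
    if isinstance(fasta, str) and fasta.lstrip().startswith(">"):
        handle = StringIO(fasta)
    elif isinstance(fasta, str) and "\n" in fasta:
        raise ReferenceError("input text does not look like FASTA (no '>' header)")
    else:
        handle = _open_maybe_gzip(fasta)

    genes: list[TrnaGene] = []
    with handle:
        for record in SeqIO.parse(handle, "fasta"):
            header = record.description or record.id
            if "intron" in header.lower():
                raise ReferenceError(
                    f"record {record.id!r} marks an intron; supply intron-less "
                    "gene or mature sequences"
                )
            m = _HEADER_RE.search(header)
            if m is None:
                raise ReferenceError(
                    f"record {record.id!r}: header lacks a tRNA-<AA>-<Anticodon> token"
                )
            amino_acid, anticodon = m.group(1), m.group(2).upper()
            if "pseudo" in header.lower():
                logger.warning("dropping pseudogene-flagged record %s", record.id)
                continue
            if anticodon == "NNN" or amino_acid.lower() in {"und", "undet"}:
                logger.warning("dropping undetermined-anticodon record %s", record.id)
                continue
            if amino_acid not in _AA_CODES:
                raise ReferenceError(
                    f"record {record.id!r}: unrecognized amino-acid class {amino_acid!r}"
                )
            seq = str(record.seq).upper().replace("U", "T")
            genes.append(
                TrnaGene(
                    gene_id=record.id,
                    amino_acid=amino_acid,
                    anticodon=anticodon,
                    sequence=seq,
                    is_spike_in=is_spike_in,
                )
            )
    return genes


def mature_sequence(seq: str, *, assume_genomic: bool = True) -> str:
    """Append the post-transcriptional 3' CCA.

    Genomic tRNA genes do not encode the CCA end, so with
    ``assume_genomic=True`` (default) CCA is appended unconditionally.  With
    ``assume_genomic=False`` the input is taken as possibly mature and CCA
    is appended only when absent.
    """
    if not assume_genomic and seq.endswith("CCA"):
        return seq
    return seq + "CCA"


def _hamming_3p_anchored(a: str, b: str) -> int:
    """Mismatches between two sequences over their 3'-anchored overlap."""
    n = min(len(a), len(b))
    ta, tb = a[-n:], b[-n:]
    return sum(x != y for x, y in zip(ta, tb))


def build_reference(
    genes: Iterable[TrnaGene],
    spike_in: TrnaGene,
    *,
    assume_genomic: bool = True,
    max_mismatches: int = 1,
) -> ChargeRefIndex:
    """Deduplicate, CCA-append and group genes into a ChargeRefIndex.

    The spike-in must differ from every cellular mature sequence by more
    than ``max_mismatches`` over their 3'-anchored overlap, otherwise spike
    normalization would be confounded by cross-mapping reads.
    """
    genes = list(genes)
    if not genes:
        raise ReferenceError("reference requires at least one non-spike gene")

    gene_map: dict[str, TrnaGene] = {}
    for g in genes:
        if g.is_spike_in:
            raise ReferenceError(f"{g.gene_id}: spike-in passed in the cellular gene list")
        if g.gene_id in gene_map or g.gene_id == spike_in.gene_id:
            raise ReferenceError(f"duplicate gene identifier {g.gene_id!r}")
        gene_map[g.gene_id] = g

    mature: dict[str, set[str]] = {}
    gene_to_mature: dict[str, str] = {}
    for g in genes:
        mat = mature_sequence(g.sequence, assume_genomic=assume_genomic)
        mature.setdefault(mat, set()).add(g.gene_id)
        gene_to_mature[g.gene_id] = mat

    spike_mat = mature_sequence(spike_in.sequence, assume_genomic=assume_genomic)
    for mat in mature:
        if _hamming_3p_anchored(spike_mat, mat) <= max_mismatches:
            close = sorted(mature[mat])
            raise ReferenceError(
                f"spike-in within {max_mismatches} mismatch(es) of reference "
                f"sequence shared by {close}; spike must be distinguishable"
            )

    by_key: dict[str, dict[str, set[str]]] = {}
    for g in genes:
        slot = by_key.setdefault(g.isodecoder_key, {"gene_ids": set(), "seqs": set()})
        slot["gene_ids"].add(g.gene_id)
        slot["seqs"].add(gene_to_mature[g.gene_id])
    isodecoders = {
        key: IsodecoderGroup(
            key=key,
            gene_ids=frozenset(slot["gene_ids"]),
            unique_sequences=frozenset(slot["seqs"]),
        )
        for key, slot in sorted(by_key.items())
    }

    spike = TrnaGene(
        gene_id=spike_in.gene_id,
        amino_acid=spike_in.amino_acid,
        anticodon=spike_in.anticodon,
        sequence=spike_in.sequence,
        is_spike_in=True,
    )
    return ChargeRefIndex(
        genes=gene_map,
        mature_sequences={k: frozenset(v) for k, v in mature.items()},
        isodecoders=isodecoders,
        spike_in=spike,
        spike_mature=spike_mat,
        gene_to_mature=gene_to_mature,
    )


def sequence_hash(seq: str) -> str:
    return hashlib.sha1(seq.encode()).hexdigest()[:12]


def save_reference(index: ChargeRefIndex, out_dir: str | os.PathLike) -> None:
    """Write a reference bundle: reference.fasta, genes.tsv, spikein.fasta."""
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "reference.fasta"), "w") as fh:
        for mat in sorted(index.mature_sequences):
            fh.write(f">{sequence_hash(mat)}\n{mat}\n")
    with open(os.path.join(out_dir, "genes.tsv"), "w") as fh:
        fh.write("gene_id\tamino_acid\tanticodon\tisodecoder\tsequence_hash\tsequence\n")
        for gene_id in sorted(index.genes):
            g = index.genes[gene_id]
            mat = index.gene_to_mature[gene_id]
            fh.write(
                f"{g.gene_id}\t{g.amino_acid}\t{g.anticodon}\t{g.isodecoder_key}\t"
                f"{sequence_hash(mat)}\t{g.sequence}\n"
            )
    with open(os.path.join(out_dir, "spikein.fasta"), "w") as fh:
        s = index.spike_in
        fh.write(f">{s.gene_id} tRNA-{s.amino_acid}-{s.anticodon} spike-in\n{s.sequence}\n")


def load_reference(ref_dir: str | os.PathLike, *, assume_genomic: bool = True) -> ChargeRefIndex:
    """Rebuild a ChargeRefIndex from a bundle written by :func:`save_reference`."""
    genes: list[TrnaGene] = []
    with open(os.path.join(ref_dir, "genes.tsv")) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {name: i for i, name in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            genes.append(
                TrnaGene(
                    gene_id=parts[cols["gene_id"]],
                    amino_acid=parts[cols["amino_acid"]],
                    anticodon=parts[cols["anticodon"]],
                    sequence=parts[cols["sequence"]],
                )
            )
    spikes = parse_trna_fasta(os.path.join(ref_dir, "spikein.fasta"), is_spike_in=True)
    if len(spikes) != 1:
        raise ReferenceError(f"spikein.fasta must hold exactly one record, found {len(spikes)}")
    return build_reference(genes, spikes[0], assume_genomic=assume_genomic)
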