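"""Synthetic CHARGE-seq libraries and qPCR plates from a known charging state.

The simulator encodes the operative logic of the periodate-protection
assay: periodate destroys the 3' ribose of uncharged tRNAs so that, after
deacylation, only molecules that were charged at harvest can be ligated to
the 3' DNA adaptor.  An "oxidized" library therefore samples the charged
pool (gene abundance x charge fraction) while a "control" (salt-treated)
library samples the total pool; the foreign spike-in tRNA, added after the
oxidation step at a fixed amount per sample, is always ligatable and
anchors cross-library normalization.

Every emitted read pair derives from exactly one ligated molecule (no PCR
duplication model), and a truth table of ligated molecules per isodecoder
accompanies each library so that estimators can be tested for parameter
recovery.  Reverse-transcriptase misincorporation at methylated-adenine
positions (the m1A58 artifact that motivates the aligner's one-mismatch
allowance) is modeled as a substitution at designated positions.
"""

from __future__ import annotations

import gzip
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chemistry import ADAPTOR_3P, ADAPTOR_RT
from .reference import (
    ChargeRefIndex,
    TrnaGene,
    build_reference,
    reverse_complement,
)

OXIDIZED = "oxidized"
CONTROL = "control"
SPIKE_LABEL = "spike_in"

_BASES = "ACGT"


class SimulationError(ValueError):
    pass


@dataclass
class ChargeProfile:
    """Ground truth: per-isodecoder charged fraction and relative abundance."""

    charge_fraction: dict[str, float]
    abundance: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.charge_fraction) != set(self.abundance):
            raise SimulationError("charge_fraction and abundance keys differ")
        for key, f in self.charge_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise SimulationError(f"{key}: charge fraction {f} outside [0, 1]")
        total = sum(self.abundance.values())
        if any(a <= 0 for a in self.abundance.values()):
            raise SimulationError("abundances must be positive")
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise SimulationError(f"abundances sum to {total}, expected 1; use from_dicts")

    @classmethod
    def from_dicts(
        cls, charge_fraction: dict[str, float], abundance: dict[str, float]
    ) -> "ChargeProfile":
        """Build a profile, normalizing abundances to sum to one."""
        total = float(sum(abundance.values()))
        if total <= 0:
            raise SimulationError("abundances must have positive total")
        return cls(dict(charge_fraction), {k: v / total for k, v in abundance.items()})

    def validate_against(self, ref: ChargeRefIndex) -> None:
        missing = set(ref.isodecoders) - set(self.charge_fraction)
        if missing:
            raise SimulationError(f"profile missing reference isodecoders: {sorted(missing)}")
        extra = set(self.charge_fraction) - set(ref.isodecoders)
        if extra:
            raise SimulationError(f"profile has unknown isodecoders: {sorted(extra)}")


@dataclass
class LibraryParams:
    n_read_pairs: int
    treatment: str
    seed: int
    read_length: int = 75
    spike_in_fraction: float = 0.05
    misincorporation_rate: float = 0.0
    modified_positions: dict[str, list[int]] | None = None
    truncation_rate: float = 0.0  # RT drop-off; off by default

    def __post_init__(self) -> None:
        if self.treatment not in (OXIDIZED, CONTROL):
            raise SimulationError(f"treatment must be {OXIDIZED!r} or {CONTROL!r}")
        if self.n_read_pairs <= 0:
            raise SimulationError("n_read_pairs must be positive")
        if not 0.0 <= self.spike_in_fraction < 0.5:
            raise SimulationError("spike_in_fraction must be in [0, 0.5)")
        if not 0.0 <= self.misincorporation_rate <= 0.25:
            raise SimulationError("misincorporation_rate must be in [0, 0.25]")


@dataclass
class QpcrSimParams:
    seed: int
    amplification_base: float = 2.0
    ct_noise_sd: float = 0.0
    baseline_ct: float = 18.0
    ct_ceiling: float = 40.0

    def __post_init__(self) -> None:
        if not 1.0 < self.amplification_base <= 2.0:
            raise SimulationError("amplification_base must be in (1, 2]")
        if self.ct_noise_sd < 0:
            raise SimulationError("ct_noise_sd must be non-negative")


def default_modified_positions(ref: ChargeRefIndex) -> dict[str, list[int]]:
    """One modified-adenine site per gene, mimicking m1A58.

    For each gene the 3'-most A in the 55-60 nt window of the mature
    sequence (0-based positions 54-59) is designated; genes with no A in
    that window carry no site.
    """
    out: dict[str, list[int]] = {}
    for gene_id, mat in ref.gene_to_mature.items():
        window = mat[54:60]
        pos = [54 + i for i, b in enumerate(window) if b == "A"]
        out[gene_id] = [pos[-1]] if pos else []
    return out


def _ligatable_weights(
    ref: ChargeRefIndex, profile: ChargeProfile, params: LibraryParams
) -> tuple[list[str], np.ndarray]:
    """Sampling distribution over ligatable molecules (genes + spike).

    The pre-treatment pool holds the spike at ``spike_in_fraction`` of
    molecules and cellular genes at abundance (uniform within an
    isodecoder's genes).  Oxidation removes the uncharged cellular
    molecules, so in an oxidized library each gene's ligatable weight is
    scaled by its isodecoder's charge fraction while the spike weight is
    untouched — which is why the spike's share of reads rises as charging
    falls.
    """
    s = params.spike_in_fraction
    labels = [ref.spike_in.gene_id]
    weights = [s]
    for key in sorted(ref.isodecoders):
        group = ref.isodecoders[key]
        a = profile.abundance[key]
        f = profile.charge_fraction[key] if params.treatment == OXIDIZED else 1.0
        per_gene = (1.0 - s) * a * f / len(group.gene_ids)
        for gene_id in sorted(group.gene_ids):
            labels.append(gene_id)
            weights.append(per_gene)
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        raise SimulationError("no ligatable molecules (all fractions zero and no spike)")
    return labels, w / total


def _open_out(path: str):
    if path.endswith(".gz"):
        return gzip.open(path, "wt")
    return open(path, "w")


def _read_pair(insert: str, read_length: int) -> tuple[str, str]:
    r1 = (insert + ADAPTOR_3P)[:read_length]
    r2 = (reverse_complement(insert) + ADAPTOR_RT)[:read_length]
    return r1, r2


def simulate_read_library(
    ref: ChargeRefIndex,
    profile: ChargeProfile,
    params: LibraryParams,
    out_dir: str | os.PathLike,
    *,
    compress: bool = False,
) -> tuple[str, str, pd.DataFrame]:
    """Emit a paired-end FASTQ library plus its ligated-molecule truth table.

    Returns ``(r1_path, r2_path, truth)`` where ``truth`` has columns
    ``isodecoder`` (or ``spike_in``), ``treatment`` and ``ligated_count``
    and its counts total exactly ``n_read_pairs``.
    """
    profile.validate_against(ref)
    min_amplicon = min(len(m) for m in ref.mature_sequences) + len(ADAPTOR_3P)
    min_amplicon = min(min_amplicon, len(ref.spike_mature) + len(ADAPTOR_3P))
    if params.read_length > min_amplicon:
        raise SimulationError(
            f"read_length {params.read_length} exceeds shortest amplicon ({min_amplicon} nt)"
        )

    rng = np.random.default_rng(params.seed)
    labels, p = _ligatable_weights(ref, profile, params)
    counts = rng.multinomial(params.n_read_pairs, p)

    modified = params.modified_positions
    if modified is None:
        modified = default_modified_positions(ref)

    os.makedirs(out_dir, exist_ok=True)
    ext = ".fastq.gz" if compress else ".fastq"
    r1_path = os.path.join(out_dir, f"R1{ext}")
    r2_path = os.path.join(out_dir, f"R2{ext}")
    qual = "I" * params.read_length

    truth_counts: dict[str, int] = {}
    idx = 0
    with _open_out(r1_path) as f1, _open_out(r2_path) as f2:
        for label, n_mol in zip(labels, counts):
            if n_mol == 0:
                continue
            if label == ref.spike_in.gene_id:
                insert = ref.spike_mature
                origin = SPIKE_LABEL
                positions: list[int] = []
            else:
                insert = ref.gene_to_mature[label]
                origin = ref.isodecoder_of(label)
                positions = [q for q in modified.get(label, []) if q < len(insert)]
            truth_counts[origin] = truth_counts.get(origin, 0) + int(n_mol)

            base_r1, base_r2 = _read_pair(insert, params.read_length)
            if positions and params.misincorporation_rate > 0:
                hit = rng.random((n_mol, len(positions))) < params.misincorporation_rate
                subs = rng.integers(0, 3, size=(n_mol, len(positions)))
            else:
                hit = None
                subs = None
            for i in range(int(n_mol)):
                if hit is not None and hit[i].any():
                    mol = list(insert)
                    for j, q in enumerate(positions):
                        if hit[i, j]:
                            choices = [b for b in _BASES if b != insert[q]]
                            mol[q] = choices[subs[i, j]]
                    r1, r2 = _read_pair("".join(mol), params.read_length)
                else:
                    r1, r2 = base_r1, base_r2
                name = f"sim:{params.treatment}:{idx:07d}:{label}:{origin}"
                f1.write(f"@{name}/1\n{r1}\n+\n{qual}\n")
                f2.write(f"@{name}/2\n{r2}\n+\n{qual}\n")
                idx += 1

    rows = [
        {"isodecoder": k, "treatment": params.treatment, "ligated_count": v}
        for k, v in sorted(truth_counts.items())
    ]
    truth = pd.DataFrame(rows, columns=["isodecoder", "treatment", "ligated_count"])
    truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)
    return r1_path, r2_path, truth


NON_OXIDIZED = "non_oxidized"


def simulate_qpcr_runs(
    profile: ChargeProfile,
    targets: list[str],
    params: QpcrSimParams,
    n_replicates: int,
) -> pd.DataFrame:
    """Simulate Ct tables for the periodate qPCR charging assay.

    For each replicate, treatment and target the template is proportional
    to abundance x charge fraction (oxidized) or abundance (non-oxidized);
    Ct = baseline - log_base(template) + Gaussian noise, and the spike Ct
    is baseline + noise only.  Zero template yields the configurable Ct
    ceiling (default 40) with ``at_ceiling`` set, never infinity.
    """
    unknown = set(targets) - set(profile.charge_fraction)
    if unknown:
        raise SimulationError(f"targets not in profile: {sorted(unknown)}")
    rng = np.random.default_rng(params.seed)
    log_base = math.log(params.amplification_base)
    rows = []
    for rep in range(1, n_replicates + 1):
        for treatment in (OXIDIZED, NON_OXIDIZED):
            for target in targets:
                template = profile.abundance[target]
                if treatment == OXIDIZED:
                    template *= profile.charge_fraction[target]
                at_ceiling = template <= 0.0
                if at_ceiling:
                    ct_t = params.ct_ceiling
                else:
                    ct_t = params.baseline_ct - math.log(template) / log_base
                    ct_t += rng.normal(0.0, params.ct_noise_sd) if params.ct_noise_sd else 0.0
                    if ct_t >= params.ct_ceiling:
                        ct_t, at_ceiling = params.ct_ceiling, True
                ct_s = params.baseline_ct
                if params.ct_noise_sd:
                    ct_s += rng.normal(0.0, params.ct_noise_sd)
                rows.append(
                    {
                        "replicate": rep,
                        "treatment": treatment,
                        "target": target,
                        "ct_target": ct_t,
                        "ct_spike": ct_s,
                        "at_ceiling": at_ceiling,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Synthetic reference and study profile
# ---------------------------------------------------------------------------

_DEFAULT_ISODECODERS = [
    ("Gln", "CTG"), ("Gln", "TTG"), ("iMet", "CAT"), ("Met", "CAT"),
    ("Ala", "AGC"), ("Arg", "ACG"), ("Asn", "GTT"), ("Asp", "GTC"),
    ("Cys", "GCA"), ("Glu", "CTC"), ("Gly", "GCC"), ("His", "GTG"),
    ("Ile", "AAT"), ("Leu", "CAG"), ("Lys", "CTT"), ("Phe", "GAA"),
    ("Pro", "AGG"), ("Ser", "AGA"), ("Thr", "AGT"), ("Val", "AAC"),
]


def _min_3p_distance(seq: str, others: list[str]) -> int:
    best = 10**9
    for o in others:
        n = min(len(seq), len(o))
        d = sum(a != b for a, b in zip(seq[-n:], o[-n:]))
        best = min(best, d)
    return best


def synthetic_reference(
    n_isodecoders: int = 20,
    genes_per_isodecoder: int = 2,
    seed: int = 0,
    min_separation: int = 5,
) -> tuple[list[TrnaGene], TrnaGene]:
    """Generate a synthetic tRNA gene set plus a distinguishable spike-in.

    Isodecoder consensus sequences are random tRNA-length (72-90 nt)
    sequences carrying their anticodon at positions 35-37 and separated
    pairwise by at least ``min_separation`` mismatches over the 3'-anchored
    overlap the aligner uses.  Within an isodecoder, even-numbered gene
    copies are exact duplicates of the consensus (exercising sequence
    deduplication and within-isodecoder multimapping) and odd-numbered
    copies carry one 5'-region substitution.
    """
    if n_isodecoders > len(_DEFAULT_ISODECODERS):
        raise SimulationError(f"at most {len(_DEFAULT_ISODECODERS)} isodecoders supported")
    rng = np.random.default_rng(seed)
    accepted: list[str] = []
    genes: list[TrnaGene] = []

    def random_body(length: int) -> str:
        return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))

    for aa, anticodon in _DEFAULT_ISODECODERS[:n_isodecoders]:
        while True:
            length = int(rng.integers(72, 91))
            body = list(random_body(length))
            body[34:37] = list(anticodon)
            consensus = "".join(body)
            if _min_3p_distance(consensus + "CCA", accepted) >= min_separation:
                accepted.append(consensus + "CCA")
                break
        for copy in range(1, genes_per_isodecoder + 1):
            seq = consensus
            if copy % 2 == 0:
                pos = int(rng.integers(3, 30))
                old = seq[pos]
                seq = seq[:pos] + _BASES[(_BASES.index(old) + 1) % 4] + seq[pos + 1:]
            genes.append(
                TrnaGene(
                    gene_id=f"synth_tRNA-{aa}-{anticodon}-{copy}-1",
                    amino_acid=aa,
                    anticodon=anticodon,
                    sequence=seq,
                )
            )
    while True:
        length = int(rng.integers(74, 80))
        body = list(random_body(length))
        body[34:37] = list("GAA")
        spike_seq = "".join(body)
        if _min_3p_distance(spike_seq + "CCA", accepted) >= min_separation:
            break
    spike = TrnaGene(
        gene_id="yeast_tRNA-Phe-GAA-spike",
        amino_acid="Phe",
        anticodon="GAA",
        sequence=spike_seq,
        is_spike_in=True,
    )
    return genes, spike


def synthetic_index(
    n_isodecoders: int = 20,
    genes_per_isodecoder: int = 2,
    seed: int = 0,
    min_separation: int = 5,
) -> ChargeRefIndex:
    genes, spike = synthetic_reference(
        n_isodecoders, genes_per_isodecoder, seed, min_separation
    )
    return build_reference(genes, spike)


def study_profile(ref: ChargeRefIndex) -> ChargeProfile:
    """The charging state used for parameter-recovery runs.

    The two glutamine isodecoders are set to charge fraction 0.05 — the
    selective-uncharging condition in which tRNA-Gln is the sole depleted
    class — while the remaining isodecoders cycle through 0.25, 0.50, 0.75
    and 0.95 so the fraction grid spans 0.05-0.95.  Abundances are uneven
    (roughly 0.5-9% of the pool) and two isodecoders are deliberately rare
    (<1%) to exercise low-abundance behavior.
    """
    keys = sorted(ref.isodecoders)
    grid = [0.25, 0.5, 0.75, 0.95]
    charge: dict[str, float] = {}
    weight: dict[str, float] = {}
    j = 0
    for i, key in enumerate(keys):
        if key.startswith("Gln-"):
            charge[key] = 0.05
        else:
            charge[key] = grid[j % len(grid)]
            j += 1
        weight[key] = 0.25 if i in (3, 11) else 1.0 + (i % 5)
    return ChargeProfile.from_dicts(charge, weight)
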