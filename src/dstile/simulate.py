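"""Synthetic fixtures with known ground truth.

Two generators: random transcriptomes into which a mutated copy of a
target block can be planted (to exercise the off-target screen with a
known answer), and replicate Cq tables drawn under a known per-group fold
change (to exercise the ddCt pipeline).  Everything is reproducible from a
single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .quant import CqRecord
from .seq_io import Sequence, Transcriptome

__all__ = [
    "PlantSpec",
    "CqSimSpec",
    "make_transcriptome",
    "plant_offtarget",
    "simulate_cq",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantSpec:
    """How to plant a mutated copy of a target block into a host transcript."""

    block_len: int
    source_start: int
    host_transcript_id: str
    substitution_rate: float = 0.0
    indel_rate: float = 0.0
    host_position: Optional[int] = None  # None -> drawn from the RNG
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_len < 1:
            raise ValueError("block_len must be >= 1")
        if self.source_start < 0:
            raise ValueError("source_start must be >= 0")
        for name, rate in (
            ("substitution_rate", self.substitution_rate),
            ("indel_rate", self.indel_rate),
        ):
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")


@dataclass(frozen=True)
class CqSimSpec:
    """Ground truth of a simulated qPCR experiment.

    ``groups`` maps each group label to per-gene true fold changes vs the
    calibrator group (genes not listed default to fold 1).  The reference
    gene must have fold 1 everywhere; the calibrator group must have fold
    1 for every gene.
    """

    groups: Mapping[str, Mapping[str, float]]
    calibrator_group: str
    reference_gene: str
    baseline_cq: Mapping[str, float]
    n_replicates: int = 5
    sigma: float = 0.2
    efficiency: Mapping[str, float] | float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.calibrator_group not in self.groups:
            raise ValueError(
                f"calibrator group {self.calibrator_group!r} not among groups"
            )
        if self.reference_gene not in self.baseline_cq:
            raise ValueError("reference gene needs a baseline cq")
        for grp, genes in self.groups.items():
            for gene, fold in genes.items():
                if fold <= 0:
                    raise ValueError(f"true fold must be > 0 ({grp}/{gene})")
                if gene == self.reference_gene and fold != 1.0:
                    raise ValueError("reference gene must have fold 1 in every group")
                if grp == self.calibrator_group and fold != 1.0:
                    raise ValueError("calibrator group must have fold 1 for every gene")
        for gene, e in self._efficiency_map().items():
            if e <= 1.0:
                raise ValueError(f"efficiency must be > 1 (gene {gene!r}, E={e})")

    def _efficiency_map(self) -> dict[str, float]:
        if isinstance(self.efficiency, Mapping):
            missing = [g for g in self.baseline_cq if g not in self.efficiency]
            if missing:
                raise ValueError(f"no efficiency for gene(s) {missing}")
            return {g: float(e) for g, e in self.efficiency.items()}
        return {g: float(self.efficiency) for g in self.baseline_cq}


def make_transcriptome(
    n_transcripts: int,
    length_range: tuple[int, int],
    gc: float = 0.5,
    seed: int = 0,
    id_prefix: str = "tx",
) -> Transcriptome:
    """Random transcriptome with i.i.d. bases at the requested GC content."""
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid length range ({lo}, {hi})")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    tx = Transcriptome()
    for i in range(n_transcripts):
        length = int(rng.integers(lo, hi + 1))
        residues = "".join(rng.choice(_BASES, size=length, p=p))
        tx.add(Sequence(f"{id_prefix}{i + 1}", residues))
    return tx


def _mutate_block(block: str, spec: PlantSpec, rng: np.random.Generator) -> tuple[str, int]:
    """Apply per-base substitutions and length-1 indels; returns the mutated
    block and the number of mutation events."""
    out = []
    n_events = 0
    for base in block:
        if spec.indel_rate > 0 and rng.random() < spec.indel_rate:
            n_events += 1
            if rng.random() < 0.5:
                continue  # deletion
            out.append(str(rng.choice(_BASES)))  # insertion before the base
            out.append(base)
            continue
        if spec.substitution_rate > 0 and rng.random() < spec.substitution_rate:
            n_events += 1
            choices = [b for b in "ACGT" if b != base]
            out.append(choices[int(rng.integers(0, 3))])
        else:
            out.append(base)
    return "".join(out), n_events


def plant_offtarget(
    transcriptome: Transcriptome,
    target: Sequence,
    spec: PlantSpec,
    k: int = 19,
) -> tuple[Transcriptome, dict]:
    """Overwrite part of a host transcript with a mutated copy of
    ``target[source_start : source_start + block_len)``.

    Returns a new transcriptome (input is not modified) and a truth record
    with the planted position and, for the zero-mutation case, the target
    fragment starts whose k-mers lie fully inside the copied block.
    """
    if spec.source_start + spec.block_len > len(target):
        raise ValueError("block extends past the end of the target")
    if spec.host_transcript_id not in transcriptome:
        raise ValueError(f"host transcript {spec.host_transcript_id!r} not found")
    host = transcriptome[spec.host_transcript_id]
    rng = np.random.default_rng(spec.seed)

    block = target.residues[spec.source_start : spec.source_start + spec.block_len]
    mutated, n_events = _mutate_block(block, spec, rng)
    if len(mutated) > len(host):
        raise ValueError(
            f"planted block ({len(mutated)} nt) longer than host "
            f"{host.id!r} ({len(host)} nt)"
        )
    if spec.host_position is None:
        pos = int(rng.integers(0, len(host) - len(mutated) + 1))
    else:
        pos = spec.host_position
        if pos < 0 or pos + len(mutated) > len(host):
            raise ValueError("host_position places the block out of bounds")

    new_residues = host.residues[:pos] + mutated + host.residues[pos + len(mutated):]
    entries = dict(transcriptome.entries)
    entries[host.id] = Sequence(host.id, new_residues)
    planted = Transcriptome(entries=entries, target_ids=set(transcriptome.target_ids))

    truth = {
        "host_transcript_id": host.id,
        "host_position": pos,
        "source_start": spec.source_start,
        "block_len": spec.block_len,
        "mutated_len": len(mutated),
        "n_mutation_events": n_events,
        "k": k,
        "flagged_fragment_starts_zero_mutation": [
            s
            for s in range(spec.source_start, spec.source_start + spec.block_len - k + 1)
        ],
    }
    return planted, truth


def simulate_cq(spec: CqSimSpec) -> list[CqRecord]:
    """Draw a replicate Cq table under the spec's ground truth.

    For each gene the cycle shift of a true fold f is -log_E(f) (fold 0.5
    at E=2 is one cycle later); Gaussian noise of sd ``sigma`` cycles is
    added independently per measurement.
    """
    rng = np.random.default_rng(spec.seed)
    eff = spec._efficiency_map()
    records: list[CqRecord] = []
    for group in spec.groups:
        folds = spec.groups[group]
        for rep in range(1, spec.n_replicates + 1):
            sample = f"{group}_r{rep}"
            for gene, baseline in spec.baseline_cq.items():
                fold = float(folds.get(gene, 1.0))
                shift = -np.log(fold) / np.log(eff[gene])
                noise = rng.normal(0.0, spec.sigma) if spec.sigma > 0 else 0.0
                records.append(
                    CqRecord(
                        sample_id=sample,
                        group=group,
                        gene=gene,
                        replicate=rep,
                        cq=float(baseline + shift + noise),
                    )
                )
    return records
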