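"""454-style pyrosequencing read simulator with full provenance.

Reads are generated in two stages, mirroring how a pyrosequencer sees a
shotgun library:

1. *Clone draw* — a fragment length is sampled from Normal(clone_mean,
   clone_sd), rounded and truncated to the source record, placed uniformly
   and on a uniform strand.
2. *Flow simulation* — the sequencer flows nucleotides in a fixed order
   (TACG) for a budget of flow cycles. Each flow reads the entire
   homopolymer run of the flowed base at the current template position:
   a run of length h >= 1 yields a signal ~ Normal(h, sigma_scale*sqrt(h)),
   while an empty (negative) flow yields a small lognormal background
   signal. The called run length is the rounded signal, so homopolymer
   over- and under-calls — the characteristic 454 error mode — arise
   naturally, as do insertions when a background signal rounds up to 1.

This is a simplified flowgram model in the standard parameterisation, not
a bit-level reproduction of any particular simulator. The lognormal
background parameters are the raw-scale mean and standard deviation of
the signal (defaults 0.23 and 0.15, so ~96% of empty flows round to
zero); 99 cycles of TACG give a nominal read length around 250-270 bp on
random sequence.

Error counts per read are Levenshtein distances between the emitted read
and the template prefix actually consumed, computed with edlib.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import numpy as np

from .kmer_core import reverse_complement

__all__ = [
    "SimulatorConfig",
    "SimulatedRead",
    "draw_clone",
    "flow_simulate",
    "simulate_readset",
    "write_reads_fasta",
    "write_reads_fastq",
    "write_truth_tsv",
    "TRUTH_COLUMNS",
]

TRUTH_COLUMNS = (
    "read_id",
    "source_taxon",
    "source_record",
    "start",
    "strand",
    "clone_length",
    "n_errors",
)


@dataclass(frozen=True)
class SimulatorConfig:
    """Parameters of the clone and flow models.

    clone_mean / clone_sd : bp
        Normal fragment-length distribution (defaults 2000 / 200).
    cycles : int
        Flow cycles; each cycle flows every base of ``flow_order`` once.
    negative_flow_mean / negative_flow_sd : signal units
        Raw-scale mean and sd of the lognormal background signal on empty
        flows. Set the sd to 0 for a deterministic signal equal to the
        mean (and both to 0 to silence insertions entirely).
    positive_flow_sigma_scale : signal units per sqrt(homopolymer length)
        Width of the incorporation signal: sigma = scale * sqrt(h).
    reads_per_genome : int
        Exact reads emitted per source record.
    """

    clone_mean: float = 2000.0
    clone_sd: float = 200.0
    cycles: int = 99
    flow_order: str = "TACG"
    negative_flow_mean: float = 0.23
    negative_flow_sd: float = 0.15
    positive_flow_sigma_scale: float = 0.15
    reads_per_genome: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.clone_mean <= 0 or self.clone_sd < 0:
            raise ValueError("clone_mean must be > 0 and clone_sd >= 0")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if not self.flow_order:
            raise ValueError("flow_order must be non-empty")
        if self.negative_flow_mean < 0 or self.negative_flow_sd < 0:
            raise ValueError("negative-flow parameters must be >= 0")
        if self.positive_flow_sigma_scale < 0:
            raise ValueError("positive_flow_sigma_scale must be >= 0")
        if self.reads_per_genome < 1:
            raise ValueError("reads_per_genome must be >= 1")

    def noiseless(self) -> "SimulatorConfig":
        """Copy with all flow noise silenced (exact substrings out)."""
        return replace(
            self,
            negative_flow_mean=0.0,
            negative_flow_sd=0.0,
            positive_flow_sigma_scale=0.0,
        )

    @property
    def lognormal_params(self) -> tuple[float, float]:
        """Underlying (mu, sigma) matching the raw-scale mean and sd."""
        m, s = self.negative_flow_mean, self.negative_flow_sd
        if m <= 0:
            return (-math.inf, 0.0)
        if s == 0:
            return (math.log(m), 0.0)
        sigma2 = math.log1p((s / m) ** 2)
        return (math.log(m) - sigma2 / 2.0, math.sqrt(sigma2))


@dataclass(frozen=True)
class SimulatedRead:
    """One read plus the provenance needed to score any downstream call."""

    read_id: str
    sequence: str
    source_taxon: str
    source_record: str
    start: int  # 0-based on the forward strand of the source record
    strand: str  # "+" or "-"
    clone_length: int
    n_errors: int


def draw_clone(
    record_seq: str, config: SimulatorConfig, rng: np.random.Generator
) -> tuple[int, str, str]:
    """Sample (start, strand, clone sequence) from one source record.

    The clone length is round(Normal(clone_mean, clone_sd)) truncated to
    [1, record length]; minus-strand clones are reverse-complemented.
    """
    L = len(record_seq)
    if L < 1:
        raise ValueError("record must be non-empty")
    length = int(round(rng.normal(config.clone_mean, config.clone_sd)))
    length = max(1, min(length, L))
    start = int(rng.integers(0, L - length + 1))
    strand = "+" if rng.integers(0, 2) == 0 else "-"
    clone = record_seq[start : start + length]
    if strand == "-":
        clone = reverse_complement(clone)
    return start, strand, clone


def flow_simulate(
    template: str, config: SimulatorConfig, rng: np.random.Generator
) -> tuple[str, int, int]:
    """Run the flowgram model over a clone.

    Returns (read sequence, n_errors, consumed template bases). The flow
    budget is cycles * len(flow_order) flows; simulation stops early when
    the template is exhausted.
    """
    mu, log_sigma = config.lognormal_params
    pos_scale = config.positive_flow_sigma_scale
    n_flows = config.cycles * len(config.flow_order)
    out: list[str] = []
    pos = 0
    L = len(template)
    for f in range(n_flows):
        if pos >= L:
            break
        base = config.flow_order[f % len(config.flow_order)]
        if template[pos] == base:
            h = 1
            while pos + h < L and template[pos + h] == base:
                h += 1
            if pos_scale > 0:
                signal = rng.normal(h, pos_scale * math.sqrt(h))
            else:
                signal = float(h)
            called = max(int(math.floor(signal + 0.5)), 0)
            pos += h
        else:
            if mu == -math.inf:
                signal = 0.0
            elif log_sigma > 0:
                signal = rng.lognormal(mu, log_sigma)
            else:
                signal = math.exp(mu)
            called = max(int(math.floor(signal + 0.5)), 0)
        if called:
            out.append(base * called)
    read = "".join(out)
    consumed = template[:pos]
    if read == consumed:
        n_errors = 0
    else:
        n_errors = edlib.align(read, consumed, task="distance")["editDistance"]
    return read, n_errors, pos


def simulate_readset(
    genomes: Sequence[tuple[str, str]],
    config: SimulatorConfig,
    mapping: Optional[Mapping[str, str]] = None,
) -> list[SimulatedRead]:
    """Exactly ``reads_per_genome`` reads from every record, with truth.

    ``mapping`` translates record ids to source taxa (identity when
    omitted, i.e. one taxon per record). A single generator seeded from
    ``config.seed`` drives everything, so the whole read set is
    reproducible byte-for-byte.
    """
    if not genomes:
        raise ValueError("at least one genome record is required")
    rng = np.random.default_rng(config.seed)
    reads: list[SimulatedRead] = []
    for rec_id, seq in genomes:
        taxon = mapping.get(rec_id, rec_id) if mapping else rec_id
        for i in range(config.reads_per_genome):
            start, strand, clone = draw_clone(seq, config, rng)
            read_seq, n_errors, _ = flow_simulate(clone, config, rng)
            if not read_seq:
                # pathological all-noise-off empty flows; emit first base
                read_seq = clone[0]
                n_errors = edlib.align(read_seq, clone[:1], task="distance")[
                    "editDistance"
                ]
            reads.append(
                SimulatedRead(
                    read_id=f"{rec_id}_r{i:05d}",
                    sequence=read_seq,
                    source_taxon=taxon,
                    source_record=rec_id,
                    start=start,
                    strand=strand,
                    clone_length=len(clone),
                    n_errors=n_errors,
                )
            )
    return reads


def write_reads_fasta(reads: Iterable[SimulatedRead], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i : i + width] + "\n")


def write_reads_fastq(reads: Iterable[SimulatedRead], path, quality: str = "I") -> None:
    """FASTQ with a constant placeholder quality (qualities are never used
    downstream; offered for tool compatibility only)."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{quality * len(r.sequence)}\n")


def write_truth_tsv(reads: Iterable[SimulatedRead], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for r in reads:
            fh.write(
                f"{r.read_id}\t{r.source_taxon}\t{r.source_record}\t"
                f"{r.start}\t{r.strand}\t{r.clone_length}\t{r.n_errors}\n"
            )
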