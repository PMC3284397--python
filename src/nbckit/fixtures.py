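"""Deterministic synthetic benchmark scenarios.

Generates random training genomes, a tree-consistent eight-rank taxonomy,
and a held-out set of *novel* taxa — point-mutation derivatives of
training genomes that share a genus (and everything above it) with their
relative but carry their own strain and species labels. This mirrors a
benchmark in which roughly half the query organisms are absent from the
training database, so the right answer for their reads is a roll-up to
the correct genus or order rather than any strain.

Everything is a pure function of the scenario seed: two runs with the
same spec write byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .taxonomy import RANKS, Lineage, TaxonomyTable

__all__ = [
    "ScenarioSpec",
    "Scenario",
    "random_genome",
    "mutate_genome",
    "make_scenario",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def random_genome(length: int, gc: float, seed) -> str:
    """i.i.d. random DNA with P(G)+P(C) = ``gc`` split evenly.

    ``seed`` may be an integer or an existing numpy Generator.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    at = (1.0 - gc) / 2.0
    p = [at, gc / 2.0, gc / 2.0, at]
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def mutate_genome(genome: str, divergence: float, seed) -> str:
    """Substitute each site to a uniformly different base with probability
    ``divergence``; length is preserved (no indels)."""
    if not 0.0 <= divergence <= 1.0:
        raise ValueError(f"divergence must be in [0, 1], got {divergence}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = np.frombuffer(genome.encode("ascii"), dtype="S1").copy()
    hit = rng.random(len(arr)) < divergence
    if hit.any():
        lut = {b"A": b"CGT", b"C": b"AGT", b"G": b"ACT", b"T": b"ACG"}
        picks = rng.integers(0, 3, size=int(hit.sum()))
        idxs = np.nonzero(hit)[0]
        for i, k in zip(idxs.tolist(), picks.tolist()):
            alts = lut.get(arr[i])
            if alts is not None:
                arr[i] = alts[k : k + 1]
    return arr.tobytes().decode("ascii")


@dataclass(frozen=True)
class ScenarioSpec:
    """Shape of a synthetic benchmark.

    ``fraction_novel`` (default 0.55) is the fraction of taxa withheld
    from the training database; the novel count is
    ceil(fraction_novel * n_taxa). ``divergence`` is substitutions per
    site between a novel taxon and its in-database relative (default
    0.10, a typical within-genus nucleotide divergence). The taxonomy
    shape parameters nest taxa into genera, genera into orders (one
    family per genus, one class per order), and orders into phyla.
    """

    n_taxa: int = 20
    length_range: tuple = (50_000, 150_000)
    gc: float = 0.5
    fraction_novel: float = 0.55
    divergence: float = 0.10
    taxa_per_genus: int = 2
    genera_per_order: int = 2
    orders_per_phylum: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 1:
            raise ValueError("n_taxa must be >= 1")
        if not 0.0 <= self.fraction_novel <= 1.0:
            raise ValueError("fraction_novel must be in [0, 1]")
        if not 0.0 <= self.divergence <= 0.5:
            raise ValueError("divergence must be in [0, 0.5]")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid length_range {self.length_range}")
        if min(self.taxa_per_genus, self.genera_per_order, self.orders_per_phylum) < 1:
            raise ValueError("taxonomy shape parameters must be >= 1")
        if self.n_training < 1:
            raise ValueError(
                "fraction_novel leaves no training taxon; lower it or raise n_taxa"
            )

    @property
    def n_novel(self) -> int:
        return math.ceil(self.fraction_novel * self.n_taxa)

    @property
    def n_training(self) -> int:
        return self.n_taxa - self.n_novel

    @classmethod
    def from_json(cls, path) -> "ScenarioSpec":
        data = json.loads(Path(path).read_text())
        if "length_range" in data:
            data["length_range"] = tuple(data["length_range"])
        return cls(**data)


@dataclass
class Scenario:
    """Materialised benchmark: sequences in memory, files on request."""

    spec: ScenarioSpec
    training: list = field(default_factory=list)  # (taxon_id, genome)
    heldout: list = field(default_factory=list)  # (taxon_id, genome)
    taxonomy: TaxonomyTable = field(default_factory=TaxonomyTable)
    relatives: dict = field(default_factory=dict)  # novel taxon -> training relative

    def write(self, out_dir) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "training_fasta": out / "training.fasta",
            "training_map": out / "training_map.tsv",
            "taxonomy": out / "taxonomy.tsv",
            "heldout_fasta": out / "heldout.fasta",
            "heldout_map": out / "heldout_map.tsv",
        }
        _write_fasta(self.training, paths["training_fasta"])
        _write_map(self.training, paths["training_map"])
        self.taxonomy.save(paths["taxonomy"])
        _write_fasta(self.heldout, paths["heldout_fasta"])
        _write_map(self.heldout, paths["heldout_map"])
        return paths


def _write_fasta(records, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _write_map(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("record_id\ttaxon_id\n")
        for rec_id, _ in records:
            fh.write(f"{rec_id}\t{rec_id}\n")


def _training_lineage(i: int, spec: ScenarioSpec) -> Lineage:
    gi = i // spec.taxa_per_genus
    oi = gi // spec.genera_per_order
    pi = oi // spec.orders_per_phylum
    return Lineage(
        (
            f"T{i:03d}",
            f"species_{i:03d}",
            f"genus_{gi:03d}",
            f"family_{gi:03d}",
            f"order_{oi:03d}",
            f"class_{oi:03d}",
            f"phylum_{pi:03d}",
            "Synthetica",
        )
    )


def make_scenario(spec: ScenarioSpec, out_dir: Optional[str] = None) -> Scenario:
    """Generate training + held-out genomes and their shared taxonomy.

    Novel taxon j is a mutated copy of training taxon j mod n_training and
    inherits its lineage from genus upward; its strain and species labels
    are its own. With ``out_dir`` set, all five files (training FASTA +
    map, taxonomy TSV, held-out FASTA + map) are also written.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    scenario = Scenario(spec=spec)
    for i in range(spec.n_training):
        length = int(rng.integers(lo, hi + 1))
        genome = random_genome(length, spec.gc, rng)
        taxon = f"T{i:03d}"
        scenario.training.append((taxon, genome))
        scenario.taxonomy.add(taxon, _training_lineage(i, spec))
    for j in range(spec.n_novel):
        rel_idx = j % spec.n_training
        rel_taxon, rel_genome = scenario.training[rel_idx]
        genome = mutate_genome(rel_genome, spec.divergence, rng)
        taxon = f"N{j:03d}"
        rel_lineage = scenario.taxonomy.lineage(rel_taxon)
        lineage = Lineage((taxon, f"novel_species_{j:03d}", *rel_lineage.labels[2:]))
        scenario.heldout.append((taxon, genome))
        scenario.taxonomy.add(taxon, lineage)
        scenario.relatives[taxon] = rel_taxon
    if out_dir is not None:
        scenario.write(out_dir)
    return scenario
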