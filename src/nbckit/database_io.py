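"""Build, serialize, and load N-mer profile databases.

Training sequences arrive as FASTA plus a two-column record->taxon mapping
TSV; FASTA headers are never parsed for taxonomy (deposited headers are
too inconsistent to trust). Viral-style databases group one profile per
strain, fungal-style databases pool all records of a species into one
profile — the two grouping policies differ only in what the mapping file
is expected to contain.

The on-disk container is versioned JSON holding each profile's observed
N-mers sparsely (a dense 4^15 table would be infeasible) plus build
metadata and a SHA-256 payload digest checked on load.

Mixing training material of very different total lengths in one database
(e.g. viral genomes next to bacterial chromosomes) is discouraged: the
unsmoothed likelihood favours long genomes, so :func:`heterogeneity_warning`
flags databases whose per-taxon training sizes span more than a configurable
ratio.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO

from .kmer_core import KmerProfile, build_profile
from .taxonomy import TaxonomyTable, load_taxonomy

__all__ = [
    "ProfileDatabase",
    "read_fasta",
    "load_mapping",
    "group_records",
    "build_database",
    "build_database_from_files",
    "save_database",
    "load_database",
    "heterogeneity_warning",
    "HeterogeneityReport",
    "DatabaseHeterogeneityWarning",
    "MappingError",
    "DatabaseBuildError",
    "DatabaseIntegrityError",
    "DatabaseVersionError",
    "FORMAT_VERSION",
]

FORMAT_VERSION = 1
_FORMAT_NAME = "nbc-profile-db"


class MappingError(ValueError):
    pass


class DatabaseBuildError(ValueError):
    pass


class DatabaseIntegrityError(ValueError):
    pass


class DatabaseVersionError(ValueError):
    pass


class DatabaseHeterogeneityWarning(UserWarning):
    pass


@dataclass
class ProfileDatabase:
    """A trained classifier: one :class:`KmerProfile` per taxon.

    All profiles share the same N; ``metadata`` records the default alpha,
    grouping policy, and source-file digests so a build is auditable.
    """

    n: int
    grouping_policy: str
    profiles: dict = field(default_factory=dict)
    taxonomy_path: Optional[str] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for taxon, prof in self.profiles.items():
            if prof.n != self.n:
                raise ValueError(
                    f"profile {taxon!r} has n={prof.n}, database expects n={self.n}"
                )

    def __eq__(self, other) -> bool:
        if not isinstance(other, ProfileDatabase):
            return NotImplemented
        return (
            self.n == other.n
            and self.grouping_policy == other.grouping_policy
            and self.taxonomy_path == other.taxonomy_path
            and self.metadata == other.metadata
            and self.profiles == other.profiles
        )

    def validate_against(self, taxonomy: TaxonomyTable) -> None:
        missing = [t for t in self.profiles if t not in taxonomy]
        if missing:
            raise DatabaseBuildError(
                f"taxa absent from taxonomy: {sorted(missing)}"
            )


def read_fasta(path) -> list[tuple[str, str]]:
    """(record_id, upper-cased sequence) pairs from a FASTA file."""
    with open(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def load_mapping(path) -> dict[str, str]:
    """Two-column TSV (record_id, taxon_id), no header required."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise MappingError(f"mapping line is not two columns: {line!r}")
            if parts[0] == "record_id" and parts[1] == "taxon_id":
                continue  # optional header
            mapping[parts[0]] = parts[1]
    return mapping


def group_records(
    fasta_records: Iterable[tuple[str, str]],
    mapping: Mapping[str, str],
    policy: str = "by_species",
    strict: bool = True,
) -> dict[str, list[str]]:
    """Group sequences by their mapped taxon.

    Under ``by_strain`` each taxon label is expected to denote a single
    strain; under ``by_species`` many records may pool into one label. In
    lenient mode unmapped records are skipped (count reported via a
    warning); in strict mode they are an error.
    """
    if policy not in ("by_strain", "by_species"):
        raise ValueError(f"unknown grouping policy {policy!r}")
    grouped: dict[str, list[str]] = {}
    skipped = 0
    for rec_id, seq in fasta_records:
        taxon = mapping.get(rec_id)
        if taxon is None:
            if strict:
                raise MappingError(f"record {rec_id!r} absent from mapping")
            skipped += 1
            continue
        grouped.setdefault(taxon, []).append(seq)
    if skipped:
        warnings.warn(f"skipped {skipped} unmapped record(s)", stacklevel=2)
    return grouped


def build_database(
    grouped: Mapping[str, Sequence[str]],
    n: int = 15,
    taxonomy: Optional[TaxonomyTable] = None,
    grouping_policy: str = "by_species",
    alpha_default: float = 1.0,
    strand_policy: str = "given",
    taxonomy_path: Optional[str] = None,
    source_digests: Optional[Mapping[str, str]] = None,
    built: Optional[str] = None,
) -> ProfileDatabase:
    """One profile per taxon from grouped training sequences.

    ``built`` (an ISO timestamp) is only recorded when supplied, so default
    builds from identical inputs serialize byte-identically. Taxa whose
    every sequence is shorter than ``n`` are reported together in one error.
    """
    profiles: dict[str, KmerProfile] = {}
    offenders: list[str] = []
    for taxon in sorted(grouped):
        seqs = grouped[taxon]
        if not any(len(s) >= n for s in seqs):
            offenders.append(taxon)
            continue
        profiles[taxon] = build_profile(taxon, seqs, n, strand_policy=strand_policy)
    if offenders:
        raise DatabaseBuildError(
            f"taxa with no sequence of length >= {n}: {offenders}"
        )
    metadata = {
        "alpha_default": alpha_default,
        "strand_policy": strand_policy,
        "source_digests": dict(source_digests or {}),
    }
    if built is not None:
        metadata["built"] = built
    db = ProfileDatabase(
        n=n,
        grouping_policy=grouping_policy,
        profiles=profiles,
        taxonomy_path=taxonomy_path,
        metadata=metadata,
    )
    if taxonomy is not None:
        db.validate_against(taxonomy)
    return db


def _file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def build_database_from_files(
    fasta_path,
    mapping_path,
    taxonomy_path=None,
    n: int = 15,
    grouping_policy: str = "by_species",
    alpha_default: float = 1.0,
    strand_policy: str = "given",
    strict: bool = True,
) -> ProfileDatabase:
    """Convenience wrapper: FASTA + mapping TSV (+ taxonomy TSV) -> database."""
    records = read_fasta(fasta_path)
    mapping = load_mapping(mapping_path)
    grouped = group_records(records, mapping, policy=grouping_policy, strict=strict)
    taxonomy = load_taxonomy(taxonomy_path) if taxonomy_path else None
    digests = {
        "fasta": _file_digest(fasta_path),
        "mapping": _file_digest(mapping_path),
    }
    if taxonomy_path:
        digests["taxonomy"] = _file_digest(taxonomy_path)
    return build_database(
        grouped,
        n=n,
        taxonomy=taxonomy,
        grouping_policy=grouping_policy,
        alpha_default=alpha_default,
        strand_policy=strand_policy,
        taxonomy_path=str(taxonomy_path) if taxonomy_path else None,
        source_digests=digests,
    )


def _payload(db: ProfileDatabase) -> dict:
    return {
        "n": db.n,
        "grouping_policy": db.grouping_policy,
        "taxonomy_path": db.taxonomy_path,
        "metadata": db.metadata,
        "profiles": {
            taxon: {
                "counts": prof.counts,
                "total": prof.total,
                "source_bp": prof.source_bp,
            }
            for taxon, prof in sorted(db.profiles.items())
        },
    }


def _canonical(obj) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"))


def save_database(db: ProfileDatabase, path) -> None:
    """Write the versioned JSON container with an integrity digest."""
    payload = _payload(db)
    doc = {
        "format": _FORMAT_NAME,
        "version": FORMAT_VERSION,
        "sha256": hashlib.sha256(_canonical(payload).encode()).hexdigest(),
        "payload": payload,
    }
    Path(path).write_text(_canonical(doc) + "\n")


def load_database(path) -> ProfileDatabase:
    """Load and verify a database container; lossless inverse of save."""
    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise DatabaseIntegrityError(f"unreadable database file {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != _FORMAT_NAME:
        raise DatabaseIntegrityError(f"{path} is not a {_FORMAT_NAME} container")
    version = doc.get("version")
    if version != FORMAT_VERSION:
        raise DatabaseVersionError(
            f"{path}: container version {version} not supported "
            f"(this build reads version {FORMAT_VERSION})"
        )
    payload = doc.get("payload")
    digest = hashlib.sha256(_canonical(payload).encode()).hexdigest()
    if digest != doc.get("sha256"):
        raise DatabaseIntegrityError(f"{path}: payload digest mismatch")
    n = payload["n"]
    profiles = {
        taxon: KmerProfile(
            taxon_id=taxon,
            n=n,
            counts=dict(p["counts"]),
            total=p["total"],
            source_bp=p["source_bp"],
        )
        for taxon, p in payload["profiles"].items()
    }
    return ProfileDatabase(
        n=n,
        grouping_policy=payload["grouping_policy"],
        profiles=profiles,
        taxonomy_path=payload["taxonomy_path"],
        metadata=payload["metadata"],
    )


@dataclass
class HeterogeneityReport:
    """Extreme per-taxon training sizes in a mixed database."""

    min_taxon: str
    min_source_bp: int
    max_taxon: str
    max_source_bp: int
    ratio: float


def heterogeneity_warning(
    db: ProfileDatabase, max_ratio: float = 100.0
) -> Optional[HeterogeneityReport]:
    """Warn when per-taxon training sizes span more than ``max_ratio``.

    Advisory only (never fatal): a large spread means the length bias of
    the unsmoothed likelihood will dominate novel-read assignments, which
    is why running one read set against a mixture of databases with very
    different genome sizes is discouraged.
    """
    if not db.profiles:
        raise ValueError("empty database")
    by_bp = sorted(db.profiles.values(), key=lambda p: (p.source_bp, p.taxon_id))
    lo, hi = by_bp[0], by_bp[-1]
    if lo.source_bp <= 0:
        ratio = float("inf") if hi.source_bp > 0 else 1.0
    else:
        ratio = hi.source_bp / lo.source_bp
    if ratio <= max_ratio:
        return None
    report = HeterogeneityReport(
        min_taxon=lo.taxon_id,
        min_source_bp=lo.source_bp,
        max_taxon=hi.taxon_id,
        max_source_bp=hi.source_bp,
        ratio=ratio,
    )
    warnings.warn(
        f"database mixes very different training sizes: "
        f"{lo.taxon_id} ({lo.source_bp} bp) vs {hi.taxon_id} ({hi.source_bp} bp), "
        f"ratio {ratio:.1f} > {max_ratio:g}; the likelihood favours longer "
        f"genomes, so mixed databases are discouraged",
        DatabaseHeterogeneityWarning,
        stacklevel=2,
    )
    return report
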