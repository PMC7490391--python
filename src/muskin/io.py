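"""Study-bundle persistence and validation.

A *bundle* is a directory of plain-text files:

==================  =========================================  ========
file                contents                                   required
==================  =========================================  ========
features_dna.tsv    DNA feature table (features x samples)     yes
features_rna.tsv    RNA feature table                          no
metadata.tsv        one row per sample                         yes
taxonomy.tsv        feature_id -> phylum..genus                no
tree.nwk            rooted Newick tree over features           no
sequences.fasta     aligned D-loop / reference sequences       no
genotypes.tsv       long-format microsatellite calls           no
==================  =========================================  ========

Feature tables are classic OTU-table orientation: features as rows,
first column ``feature_id``, one column per sample.  Missing metadata
values are empty strings; booleans are ``true``/``false``.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from skbio import TreeNode

from .types import (
    DNA,
    METADATA_COLUMNS,
    RNA,
    TAXONOMY_RANKS,
    DistanceMatrix,
    FeatureTable,
    GenotypeTable,
    SampleMetadata,
    SequenceSet,
    TaxonomyTable,
)

logger = logging.getLogger(__name__)

FILE_DNA = "features_dna.tsv"
FILE_RNA = "features_rna.tsv"
FILE_METADATA = "metadata.tsv"
FILE_TAXONOMY = "taxonomy.tsv"
FILE_TREE = "tree.nwk"
FILE_SEQUENCES = "sequences.fasta"
FILE_GENOTYPES = "genotypes.tsv"

_FLOAT_COLUMNS = (
    "x_km", "y_km", "weight_g", "body_length_mm", "tail_length_mm",
    "concentration_dna", "concentration_rna",
)
_BOOL_COLUMNS = ("pregnant", "is_negative_control")


class BundleLoadError(IOError):
    """A required bundle file is missing or unreadable."""


class BundleValidationError(ValueError):
    """The bundle content violates an invariant; message lists violations."""


@dataclass
class Violation:
    kind: str
    item: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.kind}] {self.item}: {self.message}"


@dataclass
class StudyBundle:
    table_dna: FeatureTable
    metadata: SampleMetadata
    table_rna: Optional[FeatureTable] = None
    taxonomy: Optional[TaxonomyTable] = None
    tree: Optional[TreeNode] = None
    sequences: Optional[SequenceSet] = None
    genotypes: Optional[GenotypeTable] = None

    def tables(self) -> list[FeatureTable]:
        return [t for t in (self.table_dna, self.table_rna) if t is not None]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StudyBundle):
            return NotImplemented
        if not (self.table_dna == other.table_dna
                and self.table_rna == other.table_rna
                and self.metadata == other.metadata
                and self.taxonomy == other.taxonomy
                and self.sequences == other.sequences
                and self.genotypes == other.genotypes):
            return False
        mine = None if self.tree is None else _newick(self.tree)
        theirs = None if other.tree is None else _newick(other.tree)
        return mine == theirs


def _newick(tree: TreeNode) -> str:
    import io as _io

    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_bundle(bundle: StudyBundle) -> list[Violation]:
    """Collect every invariant violation; returns [] for a valid bundle.

    Never raises on invalid content.
    """
    out: list[Violation] = []
    meta = bundle.metadata
    meta_ids = set(meta.sample_ids)

    for table in bundle.tables():
        label = table.dataset_label
        if len(set(table.feature_ids)) != len(table.feature_ids):
            out.append(Violation("feature_table", label, "duplicate feature ids"))
        if len(set(table.sample_ids)) != len(table.sample_ids):
            out.append(Violation("feature_table", label, "duplicate sample ids"))
        counts = table.counts
        if not np.issubdtype(np.asarray(counts).dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                out.append(Violation("feature_table", label, "non-integer counts"))
        neg = np.argwhere(counts < 0)
        for i, j in neg:
            out.append(Violation(
                "feature_table", label,
                f"negative count at ({table.feature_ids[i]}, {table.sample_ids[j]})",
            ))
        orphans = [s for s in table.sample_ids if s not in meta_ids]
        for s in orphans:
            out.append(Violation("cross_reference", s,
                                 f"sample {s!r} in {label} table has no metadata record"))

    conc = meta.frame[["concentration_dna", "concentration_rna"]].astype(float)
    for col in conc.columns:
        bad = meta.frame.index[conc[col] < 0]
        for s in bad:
            out.append(Violation("metadata", s, f"negative {col}"))

    # coordinates required for non-control samples of spatially structured
    # groups (= groups where any sample carries coordinates)
    coords = meta.coordinates().astype(float)
    has_xy = coords.notna().all(axis=1)
    for group, sub in meta.frame.groupby("group", dropna=True):
        idx = sub.index
        if has_xy.loc[idx].any():
            need = idx[~meta.is_control().loc[idx]]
            for s in need:
                if not has_xy.loc[s]:
                    out.append(Violation("metadata", s,
                                         f"missing coordinates in spatial group {group!r}"))

    if bundle.taxonomy is not None:
        known = set(bundle.taxonomy.feature_ids)
        for table in bundle.tables():
            for f in table.feature_ids:
                if f not in known:
                    out.append(Violation("taxonomy", f,
                                         f"feature {f!r} lacks a taxonomy record"))

    if bundle.tree is not None:
        tips = {t.name for t in bundle.tree.tips()}
        for table in bundle.tables():
            missing = set(table.feature_ids) - tips
            for f in sorted(missing):
                out.append(Violation("tree", f, f"feature {f!r} is not a tree tip"))
        for node in bundle.tree.traverse(include_self=False):
            if node.length is not None and node.length < 0:
                out.append(Violation("tree", str(node.name), "negative branch length"))

    if bundle.sequences is not None:
        for msg in bundle.sequences.violations():
            out.append(Violation("sequences", "", msg))

    if bundle.genotypes is not None:
        for (ind, locus), call in bundle.genotypes.calls.items():
            if len(call) != 2:
                out.append(Violation("genotypes", f"{ind}/{locus}",
                                     "genotype cell must hold exactly 2 alleles"))

    return out


def validate_distance_matrix(dm: DistanceMatrix) -> list[Violation]:
    return [Violation("distance_matrix", "", msg) for msg in dm.violations()]


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, (bool, np.bool_)):
        return "true" if value else "false"
    if isinstance(value, float) and np.isnan(value):
        return ""
    if isinstance(value, (float, np.floating)):
        return repr(float(value))
    return str(value)


def _write_table(table: FeatureTable, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("feature_id\t" + "\t".join(table.sample_ids) + "\n")
        for i, fid in enumerate(table.feature_ids):
            row = "\t".join(str(int(c)) for c in table.counts[i])
            fh.write(f"{fid}\t{row}\n")


def _write_metadata(meta: SampleMetadata, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(METADATA_COLUMNS) + "\n")
        for sid, row in meta.frame.iterrows():
            fh.write(sid + "\t" + "\t".join(_fmt(row[c]) for c in METADATA_COLUMNS) + "\n")


def _write_taxonomy(tax: TaxonomyTable, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("feature_id\t" + "\t".join(TAXONOMY_RANKS) + "\n")
        for fid, row in tax.frame.iterrows():
            fh.write(fid + "\t" + "\t".join(str(row[r]) for r in TAXONOMY_RANKS) + "\n")


def _write_fasta(seqs: SequenceSet, path: Path) -> None:
    with open(path, "w") as fh:
        if seqs.aligned:
            fh.write("; aligned\n")
        for sid in seqs.ids:
            fh.write(f">{sid}\n{seqs[sid]}\n")


def _write_genotypes(geno: GenotypeTable, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("individual_id\tlocus_id\tallele1\tallele2\n")
        for ind in geno.individuals:
            for locus in geno.loci:
                call = geno.get_call(ind, locus)
                a1, a2 = ("", "") if call is None else (str(call[0]), str(call[1]))
                fh.write(f"{ind}\t{locus}\t{a1}\t{a2}\n")


def write_bundle(bundle: StudyBundle, directory: str | Path) -> list[tuple[str, str]]:
    """Serialize ``bundle`` into ``directory``; returns a (path, sha256)
    manifest.  Serialization is byte-stable: writing the same bundle twice
    yields identical checksums.
    """
    violations = validate_bundle(bundle)
    if violations:
        raise BundleValidationError(
            "cannot write invalid bundle:\n" + "\n".join(map(str, violations)))

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: list[tuple[str, str]] = []

    def _emit(name: str, writer, obj) -> None:
        path = directory / name
        writer(obj, path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest.append((name, digest))

    _emit(FILE_DNA, _write_table, bundle.table_dna)
    if bundle.table_rna is not None:
        _emit(FILE_RNA, _write_table, bundle.table_rna)
    _emit(FILE_METADATA, _write_metadata, bundle.metadata)
    if bundle.taxonomy is not None:
        _emit(FILE_TAXONOMY, _write_taxonomy, bundle.taxonomy)
    if bundle.tree is not None:
        _emit(FILE_TREE, lambda t, p: p.write_text(_newick(t)), bundle.tree)
    if bundle.sequences is not None:
        _emit(FILE_SEQUENCES, _write_fasta, bundle.sequences)
    if bundle.genotypes is not None:
        _emit(FILE_GENOTYPES, _write_genotypes, bundle.genotypes)

    logger.info("wrote bundle to %s (%d files)", directory, len(manifest))
    return manifest


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_table(path: Path, dataset_label: str) -> FeatureTable:
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    return FeatureTable(
        list(frame.index.astype(str)), list(frame.columns.astype(str)),
        frame.to_numpy(dtype=np.int64), dataset_label,
    )


def _read_metadata(path: Path) -> SampleMetadata:
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    frame = frame.mask(frame == "")
    for col in _FLOAT_COLUMNS:
        if col in frame.columns:
            frame[col] = frame[col].astype(float)
    return SampleMetadata(frame)


def _read_taxonomy(path: Path) -> TaxonomyTable:
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    return TaxonomyTable(frame)


def _read_fasta(path: Path) -> SequenceSet:
    sequences: dict[str, str] = {}
    aligned = False
    current = None
    chunks: list[str] = []
    for line in path.read_text().splitlines():
        if line.startswith(";"):
            aligned = aligned or "aligned" in line
            continue
        if line.startswith(">"):
            if current is not None:
                sequences[current] = "".join(chunks)
            current = line[1:].split()[0]
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if current is not None:
        sequences[current] = "".join(chunks)
    return SequenceSet(sequences, aligned=aligned)


def _read_genotypes(path: Path) -> GenotypeTable:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    individuals = list(dict.fromkeys(frame["individual_id"]))
    loci = list(dict.fromkeys(frame["locus_id"]))
    table = GenotypeTable(individuals, loci)
    for _, row in frame.iterrows():
        if row["allele1"] != "" and row["allele2"] != "":
            table.set_call(row["individual_id"], row["locus_id"],
                           (int(row["allele1"]), int(row["allele2"])))
    return table


def load_bundle(directory: str | Path) -> StudyBundle:
    """Load and validate a bundle directory.

    Raises :class:`BundleLoadError` if a required file is missing and
    :class:`BundleValidationError` (listing every violation, including
    orphan sample ids) if the content is inconsistent.
    """
    directory = Path(directory)
    for required in (FILE_DNA, FILE_METADATA):
        if not (directory / required).exists():
            raise BundleLoadError(f"missing required bundle file: {required}")

    bundle = StudyBundle(
        table_dna=_read_table(directory / FILE_DNA, DNA),
        metadata=_read_metadata(directory / FILE_METADATA),
    )
    if (directory / FILE_RNA).exists():
        bundle.table_rna = _read_table(directory / FILE_RNA, RNA)
    if (directory / FILE_TAXONOMY).exists():
        bundle.taxonomy = _read_taxonomy(directory / FILE_TAXONOMY)
    if (directory / FILE_TREE).exists():
        bundle.tree = TreeNode.read(str(directory / FILE_TREE), format="newick")
    if (directory / FILE_SEQUENCES).exists():
        bundle.sequences = _read_fasta(directory / FILE_SEQUENCES)
    if (directory / FILE_GENOTYPES).exists():
        bundle.genotypes = _read_genotypes(directory / FILE_GENOTYPES)

    violations = validate_bundle(bundle)
    if violations:
        raise BundleValidationError(
            "bundle failed validation:\n" + "\n".join(map(str, violations)))
    logger.info("loaded bundle from %s", directory)
    return bundle


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    dm.to_frame().to_csv(path, sep="\t", float_format="%.10g")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(list(frame.index.astype(str)), frame.to_numpy(dtype=float))
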