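"""Readers/writers for the external formats the pipeline touches, plus the
canonical in-memory genome model.

Internal coordinates are **0-based, half-open** (``[start, end)``), so the
intergenic gap between two genes on a contig is simply
``next.start - prev.end``.  GFF3 input (1-based, inclusive) is converted on
read; the dialect must be named explicitly so a converted table can never be
converted twice by accident.

Formats handled here:

* gene coordinate tables — GFF3 subset (``gene``/``CDS`` features) or the
  package's 6-column TSV dialect;
* all-vs-all similarity hits — 12-column BLAST/DIAMOND tabular (outfmt 6);
* protein → GO annotations — 2-column TSV, restricted to a vocabulary;
* ARFF — nominal feature attributes in {0,1,2,3} plus binary label
  attributes, with a leading string instance-id attribute so the writer and
  reader round-trip losslessly.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("neighborgo")

GO_ID_RE = re.compile(r"^GO:\d{7}$")

#: Default 24-term photosynthesis GO vocabulary (id, human-readable name).
#: Covers photosystems, electron transport, light harvesting, pigment-protein
#: complexes and their regulation in photosynthetic prokaryotes.  Fully
#: configurable — every reader takes an explicit vocabulary.
DEFAULT_GO_VOCABULARY: tuple[tuple[str, str], ...] = (
    ("GO:0009521", "photosystem"),
    ("GO:0009522", "photosystem I"),
    ("GO:0009523", "photosystem II"),
    ("GO:0009512", "cytochrome b6f complex"),
    ("GO:0009538", "photosystem I reaction center"),
    ("GO:0009539", "photosystem II reaction center"),
    ("GO:0009579", "thylakoid"),
    ("GO:0009654", "photosystem II oxygen evolving complex"),
    ("GO:0009765", "photosynthesis, light harvesting"),
    ("GO:0009767", "photosynthetic electron transport chain"),
    ("GO:0009768", "photosynthesis, light harvesting in photosystem I"),
    ("GO:0009772", "photosynthetic electron transport in photosystem II"),
    ("GO:0009773", "photosynthetic electron transport in photosystem I"),
    ("GO:0010109", "regulation of photosynthesis"),
    ("GO:0010207", "photosystem II assembly"),
    ("GO:0016168", "chlorophyll binding"),
    ("GO:0019684", "photosynthesis, light reaction"),
    ("GO:0019685", "photosynthesis, dark reaction"),
    ("GO:0030089", "phycobilisome"),
    ("GO:0030094", "photosystem I (sensu Cyanobacteria)"),
    ("GO:0030096", "photosystem II (sensu Cyanobacteria)"),
    ("GO:0034357", "photosynthetic membrane"),
    ("GO:0042548", "regulation of photosynthesis, light reaction"),
    ("GO:0042549", "photosystem II stabilization"),
)


class ParseError(ValueError):
    """Malformed input row; the message names the offending line number."""


class ValidationError(ValueError):
    """Input violates a documented contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene locus in 0-based half-open coordinates."""

    gene_id: str
    protein_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"gene {self.gene_id}: start {self.start} < 0")
        if self.end <= self.start:
            raise ValidationError(
                f"gene {self.gene_id}: end {self.end} <= start {self.start}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def sort_key(self) -> tuple[int, int, str]:
        # deterministic tie-break: (start, end, gene_id)
        return (self.start, self.end, self.gene_id)


class GenomeCollection:
    """Genes grouped by genome and contig, sorted by coordinate.

    Every ``protein_id`` appears in exactly one genome; gene order within a
    contig is by (start, end, gene_id).  Contigs are linear by default; a
    per-contig ``circular`` flag is stored but origin-spanning neighborhoods
    are not computed.
    """

    def __init__(self) -> None:
        self.genomes: dict[str, dict[str, list[Gene]]] = {}
        self.circular: dict[tuple[str, str], bool] = {}
        self._by_protein: dict[str, Gene] = {}

    @classmethod
    def from_genes(cls, genes: Iterable[Gene]) -> "GenomeCollection":
        coll = cls()
        for g in genes:
            coll.add_gene(g)
        coll.sort()
        return coll

    def add_gene(self, gene: Gene) -> None:
        contigs = self.genomes.setdefault(gene.genome_id, {})
        contigs.setdefault(gene.contig_id, []).append(gene)
        if gene.protein_id in self._by_protein:
            prev = self._by_protein[gene.protein_id]
            if prev.genome_id != gene.genome_id:
                raise ValidationError(
                    f"protein {gene.protein_id} appears in two genomes "
                    f"({prev.genome_id}, {gene.genome_id})"
                )
        self._by_protein[gene.protein_id] = gene
        key = (gene.genome_id, gene.contig_id)
        self.circular.setdefault(key, False)

    def sort(self) -> None:
        for contigs in self.genomes.values():
            for genes in contigs.values():
                genes.sort(key=lambda g: g.sort_key)

    def gene_for_protein(self, protein_id: str) -> Gene:
        try:
            return self._by_protein[protein_id]
        except KeyError:
            raise LookupError(f"unknown protein {protein_id!r}") from None

    @property
    def protein_ids(self) -> list[str]:
        return sorted(self._by_protein)

    @property
    def genome_ids(self) -> list[str]:
        return sorted(self.genomes)

    def iter_contigs(self):
        """Yield (genome_id, contig_id, sorted gene list) deterministically."""
        for genome_id in sorted(self.genomes):
            for contig_id in sorted(self.genomes[genome_id]):
                yield genome_id, contig_id, self.genomes[genome_id][contig_id]

    def n_genes(self) -> int:
        return len(self._by_protein)


@dataclass(frozen=True)
class SimilarityHit:
    """One pairwise similarity search hit (query vs subject)."""

    query_id: str
    subject_id: str
    pct_identity: float
    e_value: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValidationError(
                f"hit {self.query_id}-{self.subject_id}: e-value < 0"
            )


@dataclass
class GOAnnotationTable:
    """protein_id → set of GO ids, restricted to an ordered vocabulary."""

    annotations: dict[str, set[str]]
    vocabulary: tuple[str, ...]
    names: Mapping[str, str] = field(default_factory=dict)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        vocab = set(self.vocabulary)
        for pid, terms in self.annotations.items():
            bad = terms - vocab
            if bad:
                raise ValidationError(
                    f"protein {pid}: terms outside vocabulary: {sorted(bad)}"
                )

    @property
    def annotated_proteins(self) -> list[str]:
        return sorted(p for p, t in self.annotations.items() if t)


def default_vocabulary() -> tuple[str, ...]:
    return tuple(go for go, _ in DEFAULT_GO_VOCABULARY)


# ---------------------------------------------------------------------------
# Gene table reading
# ---------------------------------------------------------------------------

_GFF_COLS = 9
_TSV_COLS = 6


def read_gene_table(
    path: str | Path,
    dialect: str,
    genome_id: str | None = None,
) -> GenomeCollection:
    """Read a gene coordinate table into a :class:`GenomeCollection`.

    Parameters
    ----------
    dialect
        ``"gff3"`` — 9-column GFF3, 1-based inclusive coordinates, converted
        to 0-based half-open on read (start−1); only ``gene``/``CDS``
        features are used.  ``genome_id`` defaults to the file stem.
        ``"tsv"`` — the package's 6-column dialect
        (genome_id, contig_id, protein_id, start, end, strand), already
        0-based half-open, no conversion.  The flag is mandatory so an
        already-converted table is never converted a second time.
    """
    path = Path(path)
    if dialect not in ("gff3", "tsv"):
        raise ValidationError(f"unknown dialect {dialect!r}; use 'gff3' or 'tsv'")
    genes: list[Gene] = []
    default_genome = genome_id if genome_id is not None else path.stem
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "gff3":
                    gene = _parse_gff3_row(fields, default_genome, lineno)
                    if gene is None:
                        continue
                else:
                    gene = _parse_tsv_row(fields, lineno)
            except ValidationError:
                raise
            except ParseError:
                raise
            except Exception as exc:  # malformed numerics etc.
                raise ParseError(f"{path}:{lineno}: malformed row ({exc})") from exc
            genes.append(gene)
    if not genes:
        logger.warning("gene table %s is empty", path)
    return GenomeCollection.from_genes(genes)


def _parse_gff3_row(fields: Sequence[str], genome_id: str, lineno: int) -> Gene | None:
    if len(fields) != _GFF_COLS:
        raise ParseError(f"line {lineno}: expected {_GFF_COLS} GFF3 columns, "
                         f"got {len(fields)}")
    contig, _source, ftype, start_s, end_s, _score, strand, _frame, attrs = fields
    if ftype not in ("gene", "CDS"):
        return None
    start1 = int(start_s)
    end1 = int(end_s)
    attr = dict(
        kv.split("=", 1) for kv in attrs.split(";") if kv and "=" in kv
    )
    gene_id = attr.get("ID") or attr.get("gene_id")
    if gene_id is None:
        raise ParseError(f"line {lineno}: GFF3 attributes lack ID=")
    protein_id = attr.get("protein_id", gene_id)
    gid = attr.get("genome_id", genome_id)
    start0, end0 = start1 - 1, end1  # 1-based inclusive -> 0-based half-open
    if end0 <= start0:
        raise ValidationError(f"line {lineno}: end <= start after conversion")
    return Gene(gene_id, protein_id, gid, contig, start0, end0, strand)


def _parse_tsv_row(fields: Sequence[str], lineno: int) -> Gene:
    if len(fields) != _TSV_COLS:
        raise ParseError(f"line {lineno}: expected {_TSV_COLS} TSV columns, "
                         f"got {len(fields)}")
    genome_id, contig_id, protein_id, start_s, end_s, strand = fields
    start, end = int(start_s), int(end_s)
    if end <= start:
        raise ValidationError(f"line {lineno}: end <= start")
    return Gene(protein_id, protein_id, genome_id, contig_id, start, end, strand)


def write_gene_table(collection: GenomeCollection, path: str | Path) -> None:
    """Write the 6-column TSV dialect (0-based half-open)."""
    with open(path, "w") as fh:
        for genome_id, contig_id, genes in collection.iter_contigs():
            for g in genes:
                fh.write(
                    f"{genome_id}\t{contig_id}\t{g.protein_id}\t"
                    f"{g.start}\t{g.end}\t{g.strand}\n"
                )


# ---------------------------------------------------------------------------
# Similarity hits
# ---------------------------------------------------------------------------


def read_similarity_hits(path: str | Path) -> list[SimilarityHit]:
    """Read 12-column BLAST/DIAMOND tabular hits (outfmt 6), file order kept.

    Only query, subject, %identity, e-value and bitscore are retained;
    duplicate (query, subject) pairs are kept — downstream consumers resolve
    them by minimum e-value, then maximum bitscore.
    """
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 tabular columns, got {len(fields)}"
                )
            try:
                hits.append(
                    SimilarityHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pct_identity=float(fields[2]),
                        e_value=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field ({exc})") from exc
    return hits


def write_similarity_hits(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    """Write hits as 12-column outfmt-6 (unused columns zero-filled)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:.1f}\t0\t0\t0\t"
                f"0\t0\t0\t0\t{h.e_value:.3g}\t{h.bitscore:.1f}\n"
            )


def best_hits(hits: Iterable[SimilarityHit]) -> dict[tuple[str, str], SimilarityHit]:
    """Resolve duplicate (query, subject) pairs: min e-value, tie → max bitscore."""
    best: dict[tuple[str, str], SimilarityHit] = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        prev = best.get(key)
        if prev is None or (h.e_value, -h.bitscore) < (prev.e_value, -prev.bitscore):
            best[key] = h
    return best


# ---------------------------------------------------------------------------
# GO annotations
# ---------------------------------------------------------------------------


def read_go_annotations(
    path: str | Path,
    vocabulary: Sequence[str] | None = None,
    names: Mapping[str, str] | None = None,
) -> GOAnnotationTable:
    """Read a 2-column protein↔GO TSV, restricted to ``vocabulary``.

    Terms outside the vocabulary are dropped and counted; proteins left with
    zero in-vocabulary terms are excluded from the table entirely.
    """
    if vocabulary is None:
        vocabulary = default_vocabulary()
        names = dict(DEFAULT_GO_VOCABULARY)
    vocab = tuple(vocabulary)
    vocab_set = set(vocab)
    annotations: dict[str, set[str]] = {}
    n_dropped = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            pid, go = fields
            if not GO_ID_RE.match(go):
                raise ValidationError(f"{path}:{lineno}: malformed GO id {go!r}")
            if go in vocab_set:
                annotations.setdefault(pid, set()).add(go)
            else:
                n_dropped += 1
    if n_dropped:
        logger.info("dropped %d out-of-vocabulary annotations", n_dropped)
    return GOAnnotationTable(
        annotations=annotations,
        vocabulary=vocab,
        names=names or {},
        n_dropped=n_dropped,
    )


def write_go_annotations(table: GOAnnotationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(table.annotations):
            for go in sorted(table.annotations[pid]):
                fh.write(f"{pid}\t{go}\n")


# ---------------------------------------------------------------------------
# ARFF
# ---------------------------------------------------------------------------

_ALLOWED_FEATURE_VALUES = {0, 1, 2, 3}


def write_arff(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    path: str | Path,
    relation: str = "genome_neighborhood",
) -> None:
    """Write a joint feature+label matrix as ARFF.

    Feature attributes are nominal ``{0,1,2,3}`` (quantile-binned
    conservation scores), label attributes nominal ``{0,1}``.  A leading
    string attribute carries the instance id so :func:`read_arff` can
    reconstruct both matrices losslessly.
    """
    if not features.index.equals(labels.index):
        raise ValidationError("feature and label matrices have different row ids")
    vals = set(pd.unique(features.values.ravel())) if features.size else set()
    if not vals <= _ALLOWED_FEATURE_VALUES:
        raise ValidationError(
            f"feature values outside {{0,1,2,3}}: {sorted(vals - _ALLOWED_FEATURE_VALUES)}"
        )
    if len(features) == 0:
        warnings.warn("writing header-only ARFF (0 instances)")
    with open(path, "w") as fh:
        fh.write(f"@RELATION {relation}\n\n")
        fh.write("@ATTRIBUTE instance_id string\n")
        for col in features.columns:
            fh.write(f"@ATTRIBUTE feat|{col} {{0,1,2,3}}\n")
        for col in labels.columns:
            fh.write(f"@ATTRIBUTE label|{col} {{0,1}}\n")
        fh.write("\n@DATA\n")
        for idx in features.index:
            row = [str(idx)]
            row += [str(int(v)) for v in features.loc[idx]]
            row += [str(int(v)) for v in labels.loc[idx]]
            fh.write(",".join(row) + "\n")


def read_arff(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Companion reader for :func:`write_arff`; returns (features, labels)."""
    feat_cols: list[str] = []
    label_cols: list[str] = []
    rows: list[list[str]] = []
    in_data = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            upper = line.upper()
            if upper.startswith("@RELATION"):
                continue
            if upper.startswith("@ATTRIBUTE"):
                _, name, _rest = line.split(None, 2)
                if name.startswith("feat|"):
                    feat_cols.append(name[len("feat|"):])
                elif name.startswith("label|"):
                    label_cols.append(name[len("label|"):])
                elif name != "instance_id":
                    raise ParseError(f"{path}:{lineno}: unexpected attribute {name}")
                continue
            if upper.startswith("@DATA"):
                in_data = True
                continue
            if in_data:
                rows.append(line.split(","))
    index = [r[0] for r in rows]
    nf = len(feat_cols)
    feats = pd.DataFrame(
        [[int(v) for v in r[1 : 1 + nf]] for r in rows],
        index=index, columns=feat_cols, dtype="int8",
    )
    labels = pd.DataFrame(
        [[int(v) for v in r[1 + nf :]] for r in rows],
        index=index, columns=label_cols, dtype="int8",
    )
    return feats, labels
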