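"""Variant panel, population allele counts, and read-pileup containers + TSV I/O.

The panel is a list of biallelic disease-associated loci, each with a
designated pathogenic allele.  Population allele counts are chromosome
tallies per category (e.g. gnomAD exome+genome sums) used both as point
frequencies and as Dirichlet shape parameters.  Pileups are per-individual
per-locus A/C/G/T read tallies; cells absent from the input are zero-depth,
which is legal and, in the kind of low-coverage data this package targets,
common (the motivating study had no reads at ~40% of cells).

All files are tab-separated with a header; lines starting with ``#`` are
ignored on read and used for provenance on write.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .error_model import DEFAULT_CATEGORIES

__all__ = [
    "VariantLocus",
    "VariantPanel",
    "PopulationAlleleCounts",
    "ReadPileup",
    "PileupCohort",
    "CohortSummary",
    "read_panel",
    "write_panel",
    "read_population_counts",
    "write_population_counts",
    "filter_panel_by_frequency",
    "read_pileups",
    "write_pileups",
    "read_panel_vcf",
    "cohort_summary",
]

logger = logging.getLogger(__name__)

PANEL_COLUMNS = ["locus_id", "chrom", "pos", "ref", "alt", "pathogenic_allele", "condition"]


@dataclass(frozen=True)
class VariantLocus:
    """One biallelic disease-associated locus.

    ``locus_id`` is an opaque unique key (e.g. ``"21:33974609G>C"``); HGVS
    aliases for other genome builds may be carried in ``synonyms``.
    """

    locus_id: str
    pathogenic_allele: str
    categories: tuple[str, ...] = DEFAULT_CATEGORIES
    condition: str = ""
    source: str = ""
    chrom: str = ""
    pos: int = 0
    ref: str = ""
    alt: str = ""
    synonyms: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.categories) < 2:
            raise ValueError(f"{self.locus_id}: need at least 2 allele categories")
        if self.pathogenic_allele not in self.categories:
            raise ValueError(
                f"{self.locus_id}: pathogenic allele {self.pathogenic_allele!r} "
                f"not among categories {self.categories}"
            )

    @property
    def pathogenic_index(self) -> int:
        return self.categories.index(self.pathogenic_allele)


class VariantPanel:
    """Ordered collection of :class:`VariantLocus` with unique ids."""

    def __init__(self, loci: Iterable[VariantLocus]):
        self.loci: list[VariantLocus] = list(loci)
        self._index = {loc.locus_id: i for i, loc in enumerate(self.loci)}
        if len(self._index) != len(self.loci):
            dups = [k for k, c in Counter(l.locus_id for l in self.loci).items() if c > 1]
            raise ValueError(f"duplicate locus_id(s) in panel: {dups}")
        cats = {loc.categories for loc in self.loci}
        if len(cats) > 1:
            raise ValueError("all panel loci must share one category set")
        self.categories: tuple[str, ...] = (
            self.loci[0].categories if self.loci else DEFAULT_CATEGORIES
        )

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def __contains__(self, locus_id: str) -> bool:
        return locus_id in self._index

    def __getitem__(self, locus_id: str) -> VariantLocus:
        return self.loci[self._index[locus_id]]

    def index_of(self, locus_id: str) -> int:
        return self._index[locus_id]

    @property
    def locus_ids(self) -> list[str]:
        return [loc.locus_id for loc in self.loci]

    @property
    def pathogenic_indices(self) -> np.ndarray:
        """Index of the pathogenic category at each locus, shape ``(L,)``."""
        return np.array([loc.pathogenic_index for loc in self.loci], dtype=int)

    def subset(self, locus_ids: Sequence[str]) -> "VariantPanel":
        return VariantPanel(self[i] for i in locus_ids)


@dataclass
class PopulationAlleleCounts:
    """Chromosome counts per category for one population, aligned by locus_id."""

    population_label: str
    locus_ids: list[str]
    counts: np.ndarray  # (L, K) non-negative ints

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != len(self.locus_ids):
            raise ValueError("counts must be (n_loci, n_categories)")
        if (self.counts < 0).any():
            raise ValueError(f"{self.population_label}: negative allele count")
        self._index = {lid: i for i, lid in enumerate(self.locus_ids)}

    def array_for(self, panel: VariantPanel) -> np.ndarray:
        """Counts re-ordered to panel locus order, shape ``(L, K)``.

        Raises ``KeyError`` naming the first panel locus missing from this
        counts table.
        """
        rows = []
        for lid in panel.locus_ids:
            if lid not in self._index:
                raise KeyError(
                    f"population {self.population_label!r} has no allele counts "
                    f"for panel locus {lid!r}"
                )
            rows.append(self._index[lid])
        return self.counts[rows]

    def frequencies(self, panel: VariantPanel) -> np.ndarray:
        """Plain count/total frequencies in panel order; zero-total rows are NaN."""
        c = self.array_for(panel).astype(float)
        tot = c.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, c / tot, np.nan)

    def posterior_mean_frequencies(self, panel: VariantPanel) -> np.ndarray:
        """Dirichlet posterior-mean frequencies ``(c_i + 1) / (sum c + K)``.

        The uniform +1 prior keeps every category possible even at loci
        where gnomAD-style tallies are zero for an allele.
        """
        c = self.array_for(panel).astype(float)
        k = c.shape[1]
        return (c + 1.0) / (c.sum(axis=1, keepdims=True) + k)


@dataclass(frozen=True)
class ReadPileup:
    """Read tally over allele categories for one (individual, locus) cell."""

    individual_id: str
    locus_id: str
    reads: tuple[int, ...]

    def __post_init__(self):
        if any(r < 0 for r in self.reads):
            raise ValueError(
                f"{self.individual_id}@{self.locus_id}: negative read count"
            )

    @property
    def depth(self) -> int:
        return int(sum(self.reads))


class PileupCohort:
    """Per-individual per-locus read counts, dense over a panel.

    ``reads`` has shape ``(n_individuals, n_loci, K)`` in panel locus order;
    cells never listed in the source file are all-zero (zero depth).
    """

    def __init__(self, individuals: Sequence[str], panel: VariantPanel,
                 reads: np.ndarray):
        self.individuals = list(individuals)
        self.panel = panel
        reads = np.asarray(reads, dtype=np.int64)
        expected = (len(self.individuals), len(panel), len(panel.categories))
        if reads.shape != expected:
            raise ValueError(f"reads shape {reads.shape} != {expected}")
        if (reads < 0).any():
            raise ValueError("negative read count in cohort")
        self.reads = reads

    @property
    def depths(self) -> np.ndarray:
        """Total read depth per (individual, locus), shape ``(N, L)``."""
        return self.reads.sum(axis=-1)

    def pileup(self, individual_id: str, locus_id: str) -> ReadPileup:
        i = self.individuals.index(individual_id)
        j = self.panel.index_of(locus_id)
        return ReadPileup(individual_id, locus_id, tuple(int(x) for x in self.reads[i, j]))

    def subset_loci(self, panel: VariantPanel) -> "PileupCohort":
        """Restrict to the loci of another (filtered) panel."""
        idx = [self.panel.index_of(lid) for lid in panel.locus_ids]
        return PileupCohort(self.individuals, panel, self.reads[:, idx, :])


# ---------------------------------------------------------------------------
# TSV I/O


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str,
                           keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed TSV ({exc})") from exc


def _provenance(comment_lines: Sequence[str] | None) -> str:
    if not comment_lines:
        return ""
    return "".join(f"# {line}\n" for line in comment_lines)


def read_panel(path) -> VariantPanel:
    """Read a variant panel TSV.

    Required columns: locus_id, chrom, pos, ref, alt, pathogenic_allele,
    condition.  Input order is preserved; a duplicate locus_id or an invalid
    pathogenic allele is a hard error naming the offending line.
    """
    df = _read_tsv(path)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: panel file missing column(s) {missing}")
    loci = []
    for row in df.itertuples(index=True):
        try:
            pos = int(row.pos) if row.pos else 0
            loci.append(VariantLocus(
                locus_id=row.locus_id, pathogenic_allele=row.pathogenic_allele,
                condition=row.condition, source=str(path),
                chrom=row.chrom, pos=pos, ref=row.ref, alt=row.alt,
            ))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}, data row {row.Index + 1}: {exc}") from exc
    try:
        return VariantPanel(loci)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_panel(panel: VariantPanel, path, comment_lines=None) -> None:
    rows = [
        {"locus_id": l.locus_id, "chrom": l.chrom, "pos": l.pos, "ref": l.ref,
         "alt": l.alt, "pathogenic_allele": l.pathogenic_allele,
         "condition": l.condition}
        for l in panel
    ]
    with open(path, "w") as fh:
        fh.write(_provenance(comment_lines))
        pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(fh, sep="\t", index=False)


def read_population_counts(path, population_label: str,
                           categories: Sequence[str] = DEFAULT_CATEGORIES,
                           panel: VariantPanel | None = None) -> PopulationAlleleCounts:
    """Read per-locus chromosome counts for one population.

    Expected columns: ``locus_id`` plus one integer column per category.
    A negative count is a hard error; if ``panel`` is given, count rows for
    loci absent from the panel are skipped with a warning.
    """
    df = _read_tsv(path)
    cols = list(categories)
    missing = [c for c in ["locus_id", *cols] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: counts file missing column(s) {missing}")
    if panel is not None:
        unknown = [lid for lid in df["locus_id"] if lid not in panel]
        if unknown:
            logger.warning("%s: skipping %d count row(s) for loci not in panel: %s",
                           path, len(unknown), unknown[:5])
            df = df[df["locus_id"].isin(set(panel.locus_ids))]
    try:
        counts = df[cols].astype(np.int64).to_numpy()
    except ValueError as exc:
        raise ValueError(f"{path}: non-integer allele count ({exc})") from exc
    if (counts < 0).any():
        bad = df["locus_id"].iloc[int(np.argwhere((counts < 0).any(axis=1))[0][0])]
        raise ValueError(f"{path}: negative allele count at locus {bad}")
    return PopulationAlleleCounts(population_label, list(df["locus_id"]), counts)


def write_population_counts(counts: PopulationAlleleCounts, path,
                            categories: Sequence[str] = DEFAULT_CATEGORIES,
                            comment_lines=None) -> None:
    df = pd.DataFrame(counts.counts, columns=list(categories))
    df.insert(0, "locus_id", counts.locus_ids)
    with open(path, "w") as fh:
        fh.write(_provenance(comment_lines))
        df.to_csv(fh, sep="\t", index=False)


def filter_panel_by_frequency(panel: VariantPanel,
                              counts_a: PopulationAlleleCounts,
                              counts_b: PopulationAlleleCounts) -> VariantPanel:
    """Retain loci whose pathogenic-allele frequency is strictly higher in A.

    Frequencies are plain count/total per population.  Loci with a zero
    total count in either population carry no frequency information and are
    excluded with a warning; ties are dropped (strict inequality).  The
    operation is idempotent.
    """
    fa = counts_a.frequencies(panel)
    fb = counts_b.frequencies(panel)
    path = panel.pathogenic_indices
    keep = []
    for j, locus in enumerate(panel):
        pa, pb = fa[j, path[j]], fb[j, path[j]]
        if np.isnan(pa) or np.isnan(pb):
            logger.warning("locus %s excluded: zero total allele count in %s",
                           locus.locus_id,
                           counts_a.population_label if np.isnan(pa)
                           else counts_b.population_label)
            continue
        if pa > pb:
            keep.append(locus.locus_id)
    return panel.subset(keep)


PILEUP_COLUMNS = ["individual_id", "locus_id"]


def read_pileups(path, panel: VariantPanel,
                 individuals: Sequence[str] | None = None) -> PileupCohort:
    """Read a pileup TSV into a dense cohort.

    Expected columns: individual_id, locus_id, then one integer read-count
    column per category.  Cells not listed are zero-depth; rows for loci not
    in the panel are skipped with a warning.  ``individuals`` fixes the
    individual order (and admits all-zero individuals); by default the order
    of first appearance is used.
    """
    df = _read_tsv(path)
    cats = list(panel.categories)
    missing = [c for c in [*PILEUP_COLUMNS, *cats] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: pileup file missing column(s) {missing}")
    unknown = sorted(set(df["locus_id"]) - set(panel.locus_ids))
    if unknown:
        logger.warning("%s: skipping %d pileup row(s) at loci not in panel: %s",
                       path, int(df["locus_id"].isin(unknown).sum()), unknown[:5])
        df = df[~df["locus_id"].isin(set(unknown))]
    if individuals is None:
        individuals = list(dict.fromkeys(df["individual_id"]))
    ind_index = {ind: i for i, ind in enumerate(individuals)}
    extra = set(df["individual_id"]) - set(individuals)
    if extra:
        raise ValueError(f"{path}: pileup rows for unlisted individual(s) {sorted(extra)}")
    reads = np.zeros((len(individuals), len(panel), len(cats)), dtype=np.int64)
    try:
        vals = df[cats].astype(np.int64).to_numpy()
    except ValueError as exc:
        raise ValueError(f"{path}: non-integer read count ({exc})") from exc
    if (vals < 0).any():
        raise ValueError(f"{path}: negative read count")
    for r, (ind, lid) in enumerate(zip(df["individual_id"], df["locus_id"])):
        reads[ind_index[ind], panel.index_of(lid)] += vals[r]
    return PileupCohort(individuals, panel, reads)


def write_pileups(cohort: PileupCohort, path, sparse: bool = False,
                  comment_lines=None) -> None:
    """Write a cohort as TSV; ``sparse=True`` omits zero-depth cells."""
    cats = list(cohort.panel.categories)
    rows = []
    for i, ind in enumerate(cohort.individuals):
        for j, lid in enumerate(cohort.panel.locus_ids):
            cell = cohort.reads[i, j]
            if sparse and cell.sum() == 0:
                continue
            rows.append([ind, lid, *map(int, cell)])
    df = pd.DataFrame(rows, columns=[*PILEUP_COLUMNS, *cats])
    with open(path, "w") as fh:
        fh.write(_provenance(comment_lines))
        df.to_csv(fh, sep="\t", index=False)


def read_panel_vcf(path, pathogenic: str = "alt") -> VariantPanel:
    """Build a panel from VCF variant definitions (CHROM/POS/REF/ALT only).

    Sites are keyed as ``"chrom:pos ref>alt"``; only biallelic SNVs whose
    REF and ALT are single nucleotides are kept.  Genotype and INFO fields
    are ignored — this reads variant definitions, nothing else.
    """
    loci = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}: malformed VCF line: {line!r}")
            chrom, pos, _id, ref, alt = fields[:5]
            if len(ref) != 1 or len(alt) != 1 or ref not in DEFAULT_CATEGORIES \
                    or alt not in DEFAULT_CATEGORIES:
                logger.warning("%s: skipping non-SNV site %s:%s %s>%s",
                               path, chrom, pos, ref, alt)
                continue
            loci.append(VariantLocus(
                locus_id=f"{chrom}:{pos}{ref}>{alt}",
                pathogenic_allele=alt if pathogenic == "alt" else ref,
                chrom=chrom, pos=int(pos), ref=ref, alt=alt, source=str(path),
            ))
    return VariantPanel(loci)


@dataclass
class CohortSummary:
    """Read-count bookkeeping for a cohort joined to its panel."""

    total_reads: int
    pathogenic_reads_total: int
    n_loci_with_pathogenic_read: int
    per_locus_pathogenic_reads: dict[str, int]
    pathogenic_read_multiset: dict[int, int] = field(default_factory=dict)


def cohort_summary(cohort: PileupCohort, panel: VariantPanel | None = None) -> CohortSummary:
    """Summarize total reads and pathogenic-allele reads per locus.

    The multiset records, over loci with at least one pathogenic read, how
    many loci carry each pathogenic read total (e.g. ``{4: 1, 3: 2}`` — one
    locus with four pathogenic reads, two with three).
    """
    panel = panel or cohort.panel
    if panel is not cohort.panel:
        cohort = cohort.subset_loci(panel)
    path = panel.pathogenic_indices
    per_locus = cohort.reads[:, np.arange(len(panel)), path].sum(axis=0)
    nonzero = {lid: int(c) for lid, c in zip(panel.locus_ids, per_locus) if c > 0}
    return CohortSummary(
        total_reads=int(cohort.reads.sum()),
        pathogenic_reads_total=int(per_locus.sum()),
        n_loci_with_pathogenic_read=int((per_locus > 0).sum()),
        per_locus_pathogenic_reads=nonzero,
        pathogenic_read_multiset=dict(Counter(nonzero.values())),
    )
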