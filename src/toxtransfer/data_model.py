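"""Dataset schema, normalization, flattening and learning-example construction.

The data model mirrors a standard toxicogenomics exposure design with three
domains: rat hepatocytes exposed in vitro (time grid 2, 8, 24 h), human
hepatocytes exposed in vitro (same grid), and rat liver exposed in vivo
(3, 6, 9, 24 h). Every compound is administered at four dose levels
(control, low, medium, high) with two in vitro biological replicates and
three in vivo replicates per compound-dose.

Learning examples pair a flattened in vitro time series (the network input)
with a flattened in vivo time series (the supervised target) for the labelled
source domain (rat), and carry no target for the unlabelled target domain
(human). The flattening convention is gene-major, time-minor: the 3 (or 4)
time points of gene g occupy contiguous positions. This convention is fixed
here and serialized with every trained model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DimensionMismatchError, GeneSetMismatchError, IncompleteDesignError

# Domain identifiers and their fixed time grids (hours).
RAT_VITRO = "rat_vitro"
HUMAN_VITRO = "human_vitro"
RAT_VIVO = "rat_vivo"
DOMAINS = (RAT_VITRO, HUMAN_VITRO, RAT_VIVO)

VITRO_TIMES = (2.0, 8.0, 24.0)
VIVO_TIMES = (3.0, 6.0, 9.0, 24.0)
DOMAIN_TIMES = {RAT_VITRO: VITRO_TIMES, HUMAN_VITRO: VITRO_TIMES, RAT_VIVO: VIVO_TIMES}

DOSES = ("control", "low", "medium", "high")
DOSE_ORDER = {d: i for i, d in enumerate(DOSES)}

SOURCE = "source"
TARGET = "target"

#: Number of in vivo replicates retained after the deterministic discard rule.
VIVO_KEPT = 2


@dataclass(frozen=True)
class GeneSet:
    """An ordered, duplicate-free list of gene identifiers.

    The order fixes the feature layout of every flattened vector, so it must
    be stable across save/load.
    """

    name: str
    genes: tuple[str, ...]

    def __post_init__(self):
        genes = tuple(self.genes)
        object.__setattr__(self, "genes", genes)
        if len(genes) < 1:
            raise ValueError("GeneSet must contain at least one gene")
        if len(set(genes)) != len(genes):
            raise ValueError("GeneSet contains duplicate gene identifiers")

    def __len__(self) -> int:
        return len(self.genes)

    @classmethod
    def from_file(cls, path, name: str | None = None) -> "GeneSet":
        """Read one gene identifier per line; order is significant."""
        with open(path, "rt", encoding="utf-8") as fh:
            genes = [line.strip() for line in fh if line.strip()]
        return cls(name=name or str(path), genes=tuple(genes))

    def to_file(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            for g in self.genes:
                fh.write(g + "\n")


@dataclass
class ExposureSeries:
    """One measured time series: genes x times for a compound-dose-replicate."""

    domain: str
    compound: str
    dose: str
    replicate: int
    genes: tuple[str, ...]
    values: np.ndarray  # shape (n_genes, n_times)

    def __post_init__(self):
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.dose not in DOSES:
            raise ValueError(f"unknown dose {self.dose!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")
        self.genes = tuple(self.genes)
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.genes), len(self.times))
        if self.values.shape != expected:
            raise DimensionMismatchError(
                f"values shape {self.values.shape} != genes x times {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series contains non-finite values")

    @property
    def times(self) -> tuple[float, ...]:
        return DOMAIN_TIMES[self.domain]

    def key(self) -> tuple:
        return (self.domain, self.compound, self.dose, self.replicate)


def flatten_series(series: ExposureSeries, gene_set: GeneSet) -> np.ndarray:
    """Flatten genes x times to a vector, gene-major (gene g's times contiguous).

    Raises :class:`GeneSetMismatchError` when the series' gene order differs
    from the governing gene set.
    """
    if series.genes != gene_set.genes:
        raise GeneSetMismatchError(
            f"series genes do not match gene set {gene_set.name!r}"
        )
    return series.values.reshape(-1).copy()


def unflatten_vector(vector: np.ndarray, n_genes: int, n_times: int) -> np.ndarray:
    """Inverse of :func:`flatten_series`: vector -> genes x times matrix."""
    vector = np.asarray(vector, dtype=float)
    if vector.ndim != 1 or vector.size != n_genes * n_times:
        raise DimensionMismatchError(
            f"vector of length {vector.size} cannot form {n_genes}x{n_times}"
        )
    return vector.reshape(n_genes, n_times)


@dataclass
class Normalizer:
    """Per-gene (or global) min-max scaling parameters fitted on training compounds.

    Values outside the fitted range are clipped to [0, 1] on transform. A gene
    with zero range in the fitting scope maps to the constant 0.5.
    """

    per_gene: bool
    mins: np.ndarray  # shape (n_genes,) or (1,)
    maxs: np.ndarray

    def __post_init__(self):
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)

    def transform(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        span = self.maxs - self.mins
        out = np.empty_like(values)
        degenerate = span <= 0
        safe_span = np.where(degenerate, 1.0, span)
        out = (values - self.mins[:, None]) / safe_span[:, None]
        out = np.clip(out, 0.0, 1.0)
        if np.any(degenerate):
            out[degenerate, :] = 0.5
        return out

    def inverse_transform(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        span = self.maxs - self.mins
        safe_span = np.where(span <= 0, 0.0, span)
        return values * safe_span[:, None] + self.mins[:, None]

    def to_dict(self) -> dict:
        return {
            "per_gene": self.per_gene,
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Normalizer":
        return cls(per_gene=bool(d["per_gene"]),
                   mins=np.asarray(d["mins"], dtype=float),
                   maxs=np.asarray(d["maxs"], dtype=float))


@dataclass
class ExposureDataset:
    """A multi-domain expression dataset plus its normalization state."""

    gene_set: GeneSet
    series: list[ExposureSeries]
    normalization: Normalizer | None = None

    @property
    def compounds(self) -> tuple[str, ...]:
        return tuple(sorted({s.compound for s in self.series}))

    def get(self, domain: str, compound: str, dose: str) -> list[ExposureSeries]:
        out = [
            s
            for s in self.series
            if s.domain == domain and s.compound == compound and s.dose == dose
        ]
        return sorted(out, key=lambda s: s.replicate)

    def subset(self, compounds: Iterable[str]) -> "ExposureDataset":
        keep = set(compounds)
        return ExposureDataset(
            gene_set=self.gene_set,
            series=[s for s in self.series if s.compound in keep],
            normalization=self.normalization,
        )

    def validate_complete(self) -> None:
        """Check the full-design invariant for every compound present.

        Every compound must appear with all 4 dose levels in every domain it
        occurs in, with >=2 in vitro replicates per compound-dose and >=2 rat
        in vivo replicates.
        """
        for compound in self.compounds:
            domains = {s.domain for s in self.series if s.compound == compound}
            for domain in domains:
                minimum = 2
                for dose in DOSES:
                    reps = self.get(domain, compound, dose)
                    if len(reps) < minimum:
                        raise IncompleteDesignError(
                            f"compound {compound!r} has {len(reps)} replicate(s) "
                            f"for {domain}/{dose}; >= {minimum} required"
                        )


def _collect_fit_values(ds: ExposureDataset, fit_scope: set[str]) -> np.ndarray:
    mats = [s.values for s in ds.series if s.compound in fit_scope]
    if not mats:
        raise ValueError("fit_scope matches no compounds in the dataset")
    return np.concatenate(mats, axis=1)  # genes x (all samples in scope)


def normalize_dataset(
    raw: ExposureDataset,
    fit_scope: Iterable[str],
    per_gene: bool = True,
) -> ExposureDataset:
    """Min-max scale a dataset to [0, 1], fitting on ``fit_scope`` compounds only.

    Scaling parameters never see compounds outside ``fit_scope``; values from
    held-out compounds that fall outside the fitted range are clipped. The
    fitted parameters are stored on the returned dataset for inverse
    transformation.
    """
    fit_scope = set(fit_scope)
    if not fit_scope:
        raise ValueError("fit_scope must be non-empty")
    pooled = _collect_fit_values(raw, fit_scope)
    n_genes = len(raw.gene_set)
    if per_gene:
        mins = pooled.min(axis=1)
        maxs = pooled.max(axis=1)
    else:
        mins = np.full(n_genes, pooled.min())
        maxs = np.full(n_genes, pooled.max())
    degenerate = np.flatnonzero(maxs - mins <= 0)
    if degenerate.size:
        names = [raw.gene_set.genes[i] for i in degenerate[:5]]
        warnings.warn(
            f"{degenerate.size} gene(s) with zero range in fit scope mapped to "
            f"constant 0.5 (e.g. {names})",
            stacklevel=2,
        )
    norm = Normalizer(per_gene=per_gene, mins=mins, maxs=maxs)
    new_series = [
        replace(s, values=norm.transform(s.values)) for s in raw.series
    ]
    return ExposureDataset(gene_set=raw.gene_set, series=new_series, normalization=norm)


@dataclass
class LearningExample:
    """One flattened in vitro time series, with an in vivo target when labelled.

    ``domain_label`` routes the example through the losses: ``source`` (rat)
    examples contribute to both the in vivo prediction loss and the domain
    classification loss; ``target`` (human) examples carry no target vector
    and contribute to the domain loss only. The domain label is loss-routing
    metadata — it is never fed to the network as an input feature.
    """

    domain_label: str  # SOURCE or TARGET
    compound: str
    dose: str
    vitro_replicate: int
    vivo_replicate: int | None
    input_vector: np.ndarray  # |genes| * 3
    target_vector: np.ndarray | None  # |genes| * 4 for source, None for target

    def key(self) -> tuple:
        return (
            self.domain_label,
            self.compound,
            self.dose,
            self.vitro_replicate,
            self.vivo_replicate,
        )


def build_learning_examples(
    ds: ExposureDataset,
) -> tuple[list[LearningExample], list[LearningExample]]:
    """Construct labelled source and unlabelled target learning examples.

    For each compound-dose, the rat in vivo replicate with the highest
    replicate index is discarded (deterministically), leaving two. Each of the
    two rat in vitro replicates is paired with each retained in vivo
    replicate, giving four labelled source examples per compound-dose. The
    human in vitro data is enumerated in the same manner — each human
    replicate paired with each retained in vivo replicate index — giving an
    equal number of unlabelled target examples. Ordering is deterministic:
    (compound, dose, vitro replicate, vivo replicate).
    """
    gene_set = ds.gene_set
    source: list[LearningExample] = []
    target: list[LearningExample] = []
    for compound in ds.compounds:
        for dose in DOSES:
            rat_vitro = ds.get(RAT_VITRO, compound, dose)
            human_vitro = ds.get(HUMAN_VITRO, compound, dose)
            rat_vivo = ds.get(RAT_VIVO, compound, dose)
            if len(rat_vitro) < 2 or len(human_vitro) < 2 or len(rat_vivo) < 2:
                raise IncompleteDesignError(
                    f"compound {compound!r} dose {dose!r}: needs >=2 replicates in "
                    f"each domain (got rat vitro {len(rat_vitro)}, human vitro "
                    f"{len(human_vitro)}, rat vivo {len(rat_vivo)})"
                )
            # Keep the two lowest in vivo replicate indices (drop from the top).
            vivo_kept = rat_vivo[:VIVO_KEPT]
            for vitro in rat_vitro:
                for vivo in vivo_kept:
                    source.append(
                        LearningExample(
                            domain_label=SOURCE,
                            compound=compound,
                            dose=dose,
                            vitro_replicate=vitro.replicate,
                            vivo_replicate=vivo.replicate,
                            input_vector=flatten_series(vitro, gene_set),
                            target_vector=flatten_series(vivo, gene_set),
                        )
                    )
            for vitro in human_vitro:
                for vivo in vivo_kept:
                    target.append(
                        LearningExample(
                            domain_label=TARGET,
                            compound=compound,
                            dose=dose,
                            vitro_replicate=vitro.replicate,
                            vivo_replicate=vivo.replicate,
                            input_vector=flatten_series(vitro, gene_set),
                            target_vector=None,
                        )
                    )
    return source, target


# ---------------------------------------------------------------------------
# Tidy TSV interchange
# ---------------------------------------------------------------------------

META_COLUMNS = ("sample_id", "domain", "compound", "dose", "time_h", "replicate")


def dataset_to_frame(ds: ExposureDataset) -> pd.DataFrame:
    """One row per sample (domain, compound, dose, time, replicate); gene columns."""
    rows = []
    for s in sorted(ds.series, key=lambda s: (s.domain, s.compound, DOSE_ORDER[s.dose], s.replicate)):
        for j, t in enumerate(s.times):
            sample_id = f"{s.domain}:{s.compound}:{s.dose}:{t:g}h:r{s.replicate}"
            row = {
                "sample_id": sample_id,
                "domain": s.domain,
                "compound": s.compound,
                "dose": s.dose,
                "time_h": t,
                "replicate": s.replicate,
            }
            for g, name in enumerate(ds.gene_set.genes):
                row[name] = s.values[g, j]
            rows.append(row)
    return pd.DataFrame(rows, columns=list(META_COLUMNS) + list(ds.gene_set.genes))


def frame_to_dataset(df: pd.DataFrame, gene_set: GeneSet) -> ExposureDataset:
    """Assemble an :class:`ExposureDataset` from the tidy sample table."""
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tidy table missing columns: {missing}")
    absent = [g for g in gene_set.genes if g not in df.columns]
    if absent:
        raise GeneSetMismatchError(f"tidy table lacks gene columns: {absent[:5]}")
    series = []
    grouped = df.groupby(["domain", "compound", "dose", "replicate"], sort=True)
    for (domain, compound, dose, replicate), grp in grouped:
        grid = DOMAIN_TIMES[domain]
        grp = grp.sort_values("time_h")
        times = tuple(float(t) for t in grp["time_h"])
        if times != grid:
            raise ValueError(
                f"{domain}/{compound}/{dose}/r{replicate}: time points {times} "
                f"do not match the domain grid {grid}"
            )
        values = grp[list(gene_set.genes)].to_numpy(dtype=float).T
        series.append(
            ExposureSeries(
                domain=domain,
                compound=compound,
                dose=dose,
                replicate=int(replicate),
                genes=gene_set.genes,
                values=values,
            )
        )
    return ExposureDataset(gene_set=gene_set, series=series)


def write_dataset_tsv(ds: ExposureDataset, path) -> None:
    df = dataset_to_frame(ds)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_dataset_tsv(path, gene_set: GeneSet) -> ExposureDataset:
    df = pd.read_csv(path, sep="\t")
    present = [g for g in gene_set.genes if g in df.columns]
    for col in present:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"{path}: parse error at row {row + 2}, column {col!r}: "
                f"{df[col][row]!r} is not a number"
            )
        df[col] = numeric
    return frame_to_dataset(df, gene_set)
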