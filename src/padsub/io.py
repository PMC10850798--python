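"""Readers, writers and validated containers for the pipeline's external formats.

Expression is expected to arrive already normalized and on a log scale
(log2 microarray intensities or log-TPM); no within-pipeline normalization
is performed.  Gene identity is by case-sensitive symbol string and inputs
are assumed pre-harmonized across datasets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: minimum number of samples a dataset must contribute
MIN_DATASET_SIZE = 10

#: variant classes treated as synonymous (configurable vocabulary)
SYNONYMOUS_CLASSES = frozenset({
    "Silent", "Synonymous", "synonymous_variant", "Splice_Region_Silent",
})

#: variant classes recognized as nonsynonymous
NONSYNONYMOUS_CLASSES = frozenset({
    "Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del",
    "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins", "Splice_Site",
    "Translation_Start_Site", "Nonstop_Mutation", "missense_variant",
    "stop_gained", "frameshift_variant",
})


class ValidationError(ValueError):
    """An input object violates a pipeline invariant."""


class ParseError(ValueError):
    """A file could not be parsed into the expected structure."""


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


@dataclass
class ExpressionMatrix:
    """Gene-by-sample continuous expression with per-sample dataset labels.

    Parameters
    ----------
    values
        DataFrame indexed by unique gene symbols with unique sample-id
        columns; entries are finite log-scale expression values.
    dataset_of
        Mapping from sample id to dataset (batch) id.  Every dataset must
        cover at least :data:`MIN_DATASET_SIZE` samples unless
        ``allow_small_datasets`` is set.
    """

    values: pd.DataFrame
    dataset_of: pd.Series
    allow_small_datasets: bool = False

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated gene symbols: {dupes[:10]}")
        if v.columns.duplicated().any():
            dupes = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated sample ids: {dupes[:10]}")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite expression at gene {v.index[bad[0]]!r}, "
                f"sample {v.columns[bad[1]]!r}"
            )
        self.dataset_of = pd.Series(self.dataset_of)
        missing = [s for s in v.columns if s not in self.dataset_of.index]
        if missing:
            raise ValidationError(f"samples missing from dataset map: {missing[:10]}")
        self.dataset_of = self.dataset_of.loc[v.columns]
        sizes = self.dataset_of.value_counts()
        small = sizes[sizes < MIN_DATASET_SIZE]
        if len(small) and not self.allow_small_datasets:
            raise ValidationError(
                f"datasets with fewer than {MIN_DATASET_SIZE} samples: "
                f"{dict(small)}; pass allow_small_datasets=True to override"
            )

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def datasets(self) -> list[str]:
        seen: dict[str, None] = {}
        for d in self.dataset_of:
            seen.setdefault(d)
        return list(seen)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(samples)], self.dataset_of.loc[list(samples)],
            allow_small_datasets=True,
        )

    def dataset_samples(self, dataset: str) -> list[str]:
        return [s for s in self.samples if self.dataset_of[s] == dataset]


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. the 50 hallmark pathways or immune signatures)."""

    sets: dict[str, list[str]]
    category: str = "hallmark"

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                self.sets[name] = list(dict.fromkeys(members))

    def __len__(self) -> int:
        return len(self.sets)

    def intersect(self, genes: Sequence[str], min_size: int = 5) -> "GeneSetCollection":
        """Restrict sets to ``genes``; drop sets below ``min_size`` survivors."""
        universe = set(genes)
        kept: dict[str, list[str]] = {}
        for name, members in self.sets.items():
            present = [g for g in members if g in universe]
            if len(present) >= min_size:
                kept[name] = present
            else:
                logger.warning(
                    "dropping gene set %s: only %d of %d genes present",
                    name, len(present), len(members),
                )
        return GeneSetCollection(kept, category=self.category)


@dataclass
class PipelineConfig:
    """Tunable parameters of the consensus subtyping framework.

    Defaults follow the published protocol: five folds, 100 iterations and a
    51-nearest-neighbor out-of-sample vote.
    """

    k_folds: int = 5
    n_iterations: int = 100
    knn_predict: int = 51
    umap_neighbors: int = 30
    umap_min_dist: float = 0.3
    consensus_neighbors: int = 15
    graph_k: int = 15
    walk_steps: int = 4
    iteration_graph: str = "knn"
    consensus_graph: str = "dense"
    consensus_space: str = "scores"
    base_seed: int = 0
    gsva_kernel: str = "gaussian"
    gsva_tau: float = 1.0
    gsva_mode: str = "max_diff"
    min_set_size: int = 5
    cluster_on_embedding: bool = True

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValidationError("k_folds must be >= 2")
        if self.n_iterations < 1:
            raise ValidationError("n_iterations must be >= 1")
        if self.knn_predict < 1 or self.knn_predict % 2 == 0:
            raise ValidationError("knn_predict must be odd and >= 1")
        if self.gsva_kernel not in ("gaussian", "ecdf"):
            raise ValidationError(f"unknown kernel {self.gsva_kernel!r}")
        if self.gsva_mode not in ("max_diff", "max_deviation"):
            raise ValidationError(f"unknown score mode {self.gsva_mode!r}")
        for field_name in ("iteration_graph", "consensus_graph"):
            if getattr(self, field_name) not in ("dense", "knn"):
                raise ValidationError(
                    f"unknown {field_name} {getattr(self, field_name)!r}")
        if self.consensus_space not in ("scores", "embedding"):
            raise ValidationError(
                f"unknown consensus_space {self.consensus_space!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# GMT gene-set files
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path, category: str = "hallmark") -> GeneSetCollection:
    """Read a GMT file (one set per line: name, description, genes...).

    Duplicate gene entries within a line are deduplicated preserving order;
    the description field is discarded.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise ValidationError(f"{path}: duplicate set name {name!r}")
            genes = [g for g in fields[2:] if g]
            sets[name] = list(dict.fromkeys(genes))
    if not sets:
        warnings.warn(f"{path}: empty GMT file", stacklevel=2)
        return GeneSetCollection({}, category=category)
    return GeneSetCollection(sets, category=category)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression(
    path: str | Path,
    dataset_map_path: str | Path | None = None,
    dataset_of: Mapping[str, str] | None = None,
    allow_small_datasets: bool = False,
) -> ExpressionMatrix:
    """Read a genes-x-samples TSV/CSV plus a sample-to-dataset map.

    The dataset map is a two-column table (sample, dataset) with a header.
    Malformed numeric fields are rejected with their coordinates rather than
    silently coerced.
    """
    sep = _sep_for(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicated gene rows: {dupes[:10]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy() & df.notna().to_numpy())
    if len(bad):
        g, s = bad[0]
        raise ParseError(
            f"{path}: non-numeric value {df.iloc[g, s]!r} at gene "
            f"{df.index[g]!r}, sample {df.columns[s]!r}"
        )
    if numeric.isna().to_numpy().any():
        g, s = np.argwhere(numeric.isna().to_numpy())[0]
        raise ParseError(
            f"{path}: missing value at gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r}"
        )
    if dataset_of is None:
        if dataset_map_path is None:
            raise ValueError("either dataset_map_path or dataset_of is required")
        dmap = pd.read_csv(dataset_map_path, sep=_sep_for(dataset_map_path))
        dataset_of = pd.Series(
            dmap.iloc[:, 1].astype(str).to_numpy(),
            index=dmap.iloc[:, 0].astype(str),
        )
    return ExpressionMatrix(
        numeric.astype(float), pd.Series(dataset_of),
        allow_small_datasets=allow_small_datasets,
    )


def write_expression(expr: ExpressionMatrix, path: str | Path,
                     dataset_map_path: str | Path | None = None) -> None:
    expr.values.to_csv(path, sep=_sep_for(path), index_label="gene")
    if dataset_map_path is not None:
        expr.dataset_of.rename_axis("sample").rename("dataset").to_frame() \
            .to_csv(dataset_map_path, sep=_sep_for(dataset_map_path))


# ---------------------------------------------------------------------------
# Variant (MAF-like), clinical, CNA and drug-panel tables
# ---------------------------------------------------------------------------

#: column aliases accepted for the mandatory MAF-like fields
_MAF_ALIASES = {
    "sample": ["sample", "Tumor_Sample_Barcode", "sample_id"],
    "gene": ["gene", "Hugo_Symbol", "gene_symbol"],
    "effect": ["effect", "Variant_Classification", "variant_classification"],
}


def read_variants(path: str | Path) -> pd.DataFrame:
    """Read a MAF-like TSV into a table (sample, gene, effect, synonymous flag).

    Unknown effect classes are retained but flagged ``effect_known=False``.
    An optional ``signature`` column carrying mutational-signature
    attributions is passed through.
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    cols: dict[str, str] = {}
    for canon, aliases in _MAF_ALIASES.items():
        found = [a for a in aliases if a in df.columns]
        if not found:
            raise ParseError(f"{path}: missing mandatory column {canon!r} "
                             f"(accepted names: {aliases})")
        cols[canon] = found[0]
    out = pd.DataFrame({
        "sample": df[cols["sample"]].astype(str),
        "gene": df[cols["gene"]].astype(str),
        "effect": df[cols["effect"]].astype(str),
    })
    out["synonymous"] = out["effect"].isin(SYNONYMOUS_CLASSES)
    out["effect_known"] = out["effect"].isin(SYNONYMOUS_CLASSES | NONSYNONYMOUS_CLASSES)
    if "signature" in df.columns:
        out["signature"] = df["signature"]
    n_unknown = int((~out["effect_known"]).sum())
    if n_unknown:
        logger.warning("%s: %d variants with unrecognized effect class", path, n_unknown)
    return out


#: controlled clinical column vocabulary
CLINICAL_COLUMNS = [
    "sample", "dataset", "age", "sex", "stage", "smoking",
    "egfr", "kras", "alk", "tp53", "stk11",
    "os_time", "os_event", "response", "tide",
    "pdl1_expr", "pd1_expr", "ddr_score",
]


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path))
    if "sample" not in df.columns:
        raise ParseError(f"{path}: clinical table must have a 'sample' column")
    unknown = [c for c in df.columns if c not in CLINICAL_COLUMNS and c != "subtype"]
    if unknown:
        logger.warning("%s: ignoring unrecognized clinical columns %s", path, unknown)
    return df.set_index("sample", drop=False)


def read_cna(path: str | Path) -> pd.DataFrame:
    """Gene-by-sample integer copy-number call matrix (0 = neutral)."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    arr = df.to_numpy()
    if not np.all(np.equal(np.mod(arr, 1), 0)):
        raise ValidationError(f"{path}: copy-number calls must be integers")
    return df.astype(int)


def read_aac_panel(path: str | Path) -> pd.DataFrame:
    """Long-format AAC table with columns (study, cell_line, drug, aac)."""
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"study", "cell_line", "drug", "aac"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing AAC columns {sorted(missing)}")
    if df.duplicated(["study", "cell_line", "drug"]).any():
        raise ValidationError(f"{path}: duplicate (study, cell_line, drug) keys")
    aac = pd.to_numeric(df["aac"], errors="raise")
    if ((aac < 0) | (aac > 1)).any():
        raise ValidationError(f"{path}: AAC values must lie in [0, 1]")
    df["aac"] = aac
    return df
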