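"""Expression-table loading, noise-gene filtering, log2 normalisation, presence sets.

The central container is :class:`ExpressionDataset`, a non-negative gene ×
sample matrix whose column names encode the sample design as
``species_condition_replicate`` (e.g. ``Th_cellulose_1``). Downstream
modules (differential expression, co-expression networks) consume the
log2-normalised form produced by :func:`log2_normalize`; presence sets are
computed on the linear (pre-log) scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class InputError(ValueError):
    """Malformed input table (bad header, negative value, duplicate ID...)."""


def _parse_sample(name: str) -> tuple[str, str, int]:
    """Split a ``species_condition_rep`` column label into its three parts."""
    parts = str(name).split("_")
    if len(parts) != 3:
        raise InputError(
            f"sample column {name!r} does not parse as species_condition_rep"
        )
    species, condition, rep = parts
    try:
        rep_i = int(rep)
    except ValueError:
        raise InputError(
            f"sample column {name!r}: replicate field {rep!r} is not an integer"
        ) from None
    return species, condition, rep_i


@dataclass
class ExpressionDataset:
    """Gene × sample expression matrix with sample metadata parsed from headers.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID with one column per sample. All values
        must be finite and ≥ 0 on construction (linear scale); log2-scale
        datasets produced by :func:`log2_normalize` set ``log_scale=True``
        and may contain negative values.
    log_scale
        Whether the values are log2-transformed.
    """

    values: pd.DataFrame
    log_scale: bool = False

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate gene IDs: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise InputError(f"duplicate sample columns: {dups[:5]}")
        for c in v.columns:
            _parse_sample(c)
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            g, s = np.argwhere(~np.isfinite(arr))[0]
            raise InputError(
                f"non-finite value at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )
        if not self.log_scale and (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise InputError(
                f"negative value at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def samples(self) -> pd.DataFrame:
        """Sample metadata (species, condition, replicate), indexed by column name."""
        rows = [_parse_sample(c) for c in self.values.columns]
        return pd.DataFrame(
            rows, index=self.values.columns, columns=["species", "condition", "replicate"]
        )

    @property
    def species(self) -> list[str]:
        seen: list[str] = []
        for sp in self.samples["species"]:
            if sp not in seen:
                seen.append(sp)
        return seen

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for c in self.samples["condition"]:
            if c not in seen:
                seen.append(c)
        return seen

    def columns_for(self, species: str | None = None, condition: str | None = None) -> list[str]:
        """Sample columns matching the given species and/or condition."""
        meta = self.samples
        mask = pd.Series(True, index=meta.index)
        if species is not None:
            mask &= meta["species"] == species
        if condition is not None:
            mask &= meta["condition"] == condition
        return list(meta.index[mask])

    def subset(self, genes=None, columns=None) -> "ExpressionDataset":
        v = self.values
        if genes is not None:
            v = v.loc[list(genes)]
        if columns is not None:
            v = v[list(columns)]
        return ExpressionDataset(v.copy(), log_scale=self.log_scale)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class FilterReport:
    """Outcome of a gene-filtering step: which genes were kept and why."""

    kept: list[str]
    removed: list[str]
    rule: str

    def to_tsv(self, path) -> None:
        rows = [(g, "kept") for g in self.kept] + [(g, "removed") for g in self.removed]
        pd.DataFrame(rows, columns=["gene_id", "status"]).to_csv(path, sep="\t", index=False)


def load_expression(path) -> ExpressionDataset:
    """Read a gene × sample TSV (first column gene IDs, header sample labels)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.empty:
        raise InputError(f"{path}: no sample columns found")
    df.index = df.index.astype(str)
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise InputError(f"{path}: non-numeric expression value ({exc})") from None
    return ExpressionDataset(values)


def filter_null_genes(
    ds: ExpressionDataset,
    max_zero_fraction: float = 0.5,
    per_condition: bool = False,
) -> tuple[ExpressionDataset, FilterReport]:
    """Exclude genes that are zero in most of their samples.

    A gene is removed iff its fraction of zero values is *strictly* greater
    than ``max_zero_fraction`` — a gene zero in exactly half its samples at
    the default threshold survives. With ``per_condition=True`` the fraction
    is evaluated within each (species, condition) replicate group and the
    gene is removed only when every group exceeds the threshold.
    """
    if not 0.0 <= max_zero_fraction <= 1.0:
        raise InputError(f"max_zero_fraction must be in [0, 1], got {max_zero_fraction}")
    zero = ds.values.to_numpy() == 0
    if per_condition:
        meta = ds.samples
        groups = meta.groupby(["species", "condition"], sort=False).groups
        exceed = np.ones(len(ds.genes), dtype=bool)
        for cols in groups.values():
            idx = [ds.sample_names.index(c) for c in cols]
            frac = zero[:, idx].mean(axis=1)
            exceed &= frac > max_zero_fraction
        removed_mask = exceed
        rule = (
            f"zero fraction > {max_zero_fraction} within every species×condition group"
        )
    else:
        frac = zero.mean(axis=1)
        removed_mask = frac > max_zero_fraction
        rule = f"zero fraction > {max_zero_fraction} across all samples"
    genes = np.asarray(ds.genes)
    kept = genes[~removed_mask].tolist()
    removed = genes[removed_mask].tolist()
    filtered = ExpressionDataset(ds.values.loc[kept].copy(), log_scale=ds.log_scale)
    return filtered, FilterReport(kept=kept, removed=removed, rule=rule)


def log2_normalize(
    ds: ExpressionDataset,
    pseudocount: float = 1.0,
    normalize: bool = True,
) -> ExpressionDataset:
    """Median-total column scaling followed by log2(x + pseudocount).

    Each sample column is first rescaled so its total equals the median of
    all column totals (columns summing to zero are left untouched); the
    matrix is then log2-transformed with the given pseudocount. Pass
    ``normalize=False`` to skip the scaling step, and ``pseudocount=0`` only
    when no zeros are present.
    """
    arr = ds.values.to_numpy(dtype=float).copy()
    if normalize and arr.size:
        totals = arr.sum(axis=0)
        target = float(np.median(totals))
        nonzero = totals > 0
        arr[:, nonzero] = arr[:, nonzero] * (target / totals[nonzero])
    if arr.size and (arr + pseudocount <= 0).any():
        raise InputError(
            f"pseudocount {pseudocount} leaves non-positive values; log2 undefined"
        )
    out = np.log2(arr + pseudocount) if arr.size else arr
    return ExpressionDataset(
        pd.DataFrame(out, index=ds.values.index, columns=ds.values.columns),
        log_scale=True,
    )


def presence_sets(ds: ExpressionDataset) -> dict[tuple[str, str], set[str]]:
    """Genes expressed above zero per (species, condition) cell.

    A gene is present in a cell iff any of that cell's replicates is
    non-zero (equivalently, its replicate mean is > 0 on the linear scale).
    """
    if ds.log_scale:
        raise InputError("presence_sets expects linear-scale (pre-log) data")
    meta = ds.samples
    out: dict[tuple[str, str], set[str]] = {}
    genes = np.asarray(ds.genes)
    for (sp, cond), cols in meta.groupby(["species", "condition"], sort=False).groups.items():
        block = ds.values[list(cols)].to_numpy()
        present = (block > 0).any(axis=1)
        out[(sp, cond)] = set(genes[present])
    return out
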