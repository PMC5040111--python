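"""Probe-to-gene preprocessing for functional gene array data.

The chain is: QC filtering (flags and signal-to-noise) -> three-level
normalization (subgrids within a slide, technical replicates, across
slides) -> gene/probe detection filters -> relative-abundance rescaling
with an ln(x + 1) transform. Probe records travel as a pandas DataFrame
with the canonical columns of :data:`PROBE_COLUMNS`; after technical
replicates are averaged the slide-level columns are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical probe-table columns, in file order.
PROBE_COLUMNS = (
    "slide_id",
    "sample_id",
    "subgrid",
    "probe_id",
    "gene_id",
    "category",
    "signal",
    "background",
    "background_sd",
    "flag",
)

_NUMERIC = {"subgrid": int, "signal": float, "background": float,
            "background_sd": float, "flag": int}

#: ImaGene flag codes that mark a spot as bad.
BAD_FLAGS = frozenset({1, 3})

#: Minimum signal-to-noise ratio; spots strictly below are removed.
SNR_THRESHOLD = 2.0

#: Minimum fraction of a gene's designed probes that must be detected.
GENE_PROBE_FRACTION = 0.333

#: Minimum number of detected probes per gene.
GENE_MIN_PROBES = 2

#: Minimum number of samples a probe must be detected in.
PROBE_MIN_REPLICATES = 2


@dataclass
class GeneSignalMatrix:
    """Normalized gene x sample abundance matrix plus its probe-level parent.

    ``values`` holds ln(rescaled + 1) gene signals; ``values_linear`` the
    same quantities before the log transform. Undetected cells are 0.
    """

    values: pd.DataFrame  # genes x samples, ln(rescaled + 1)
    values_linear: pd.DataFrame  # genes x samples, rescaled signal
    categories: pd.Series  # gene_id -> category
    probe_values: pd.DataFrame  # probes x samples, ln(rescaled + 1)
    probe_values_linear: pd.DataFrame  # probes x samples, rescaled signal
    probe_genes: pd.Series  # probe_id -> gene_id
    probe_categories: pd.Series  # probe_id -> category
    designed_probe_counts: dict[str, int] | None = None

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "category", self.categories.reindex(out.index))
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @staticmethod
    def read_values_tsv(path) -> pd.DataFrame:
        """Read back the gene x sample value table written by :meth:`to_tsv`."""
        frame = pd.read_csv(path, sep="\t", index_col="gene_id")
        return frame.drop(columns=["category"])


def qc_filter_probes(
    records: pd.DataFrame,
    snr_mode: Literal["subtract", "ratio"] = "subtract",
) -> pd.DataFrame:
    """Drop flagged spots and spots with SNR below :data:`SNR_THRESHOLD`.

    ``snr_mode="subtract"`` (default) uses
    SNR = (signal - background) / background_sd; ``"ratio"`` uses
    signal / background. Spots flagged 1 or 3 are removed; SNR exactly at
    the threshold is retained.
    """
    if records.empty:
        raise ValueError("no probe records to filter")
    bad_sd = records["background_sd"] <= 0
    if bad_sd.any():
        probe = records.loc[bad_sd, "probe_id"].iloc[0]
        raise ValueError(
            f"probe {probe!r} has non-positive background_sd; SNR undefined"
        )
    if snr_mode == "subtract":
        snr = (records["signal"] - records["background"]) / records["background_sd"]
    elif snr_mode == "ratio":
        bad_bg = records["background"] <= 0
        if bad_bg.any():
            probe = records.loc[bad_bg, "probe_id"].iloc[0]
            raise ValueError(
                f"probe {probe!r} has non-positive background; ratio SNR undefined"
            )
        snr = records["signal"] / records["background"]
    else:
        raise ValueError(f"unknown snr_mode {snr_mode!r}")
    keep = ~records["flag"].isin(BAD_FLAGS) & (snr >= SNR_THRESHOLD)
    return records.loc[keep].reset_index(drop=True)


def normalize(records: pd.DataFrame) -> pd.DataFrame:
    """Three-level signal normalization.

    Stage 1 rescales each subgrid so its mean signal equals its slide's
    mean; stage 2 averages technical replicates (slides sharing a
    sample_id) per probe; stage 3 rescales each sample so its total
    intensity equals the across-sample mean total. Returns records keyed
    by (sample_id, probe_id) with slide-level columns removed.
    """
    if records.empty:
        raise ValueError("no probe records to normalize")
    work = records.copy()

    # stage 1: subgrid means -> slide mean
    slide_means = work.groupby("slide_id")["signal"].transform("mean")
    sub_means = work.groupby(["slide_id", "subgrid"])["signal"].transform("mean")
    factor = np.ones(len(work))
    ok = sub_means.to_numpy() != 0
    factor[ok] = slide_means.to_numpy()[ok] / sub_means.to_numpy()[ok]
    if not ok.all():
        zero = work.loc[~ok, ["slide_id", "subgrid"]].drop_duplicates()
        for slide, grid in zero.itertuples(index=False):
            logger.warning(
                "subgrid %s of slide %s has all-zero signals; left unscaled",
                grid, slide,
            )
    work["signal"] = work["signal"] * factor

    # stage 2: average technical replicates of the same sample x probe
    averaged = (
        work.groupby(["sample_id", "probe_id"], sort=False)
        .agg(
            gene_id=("gene_id", "first"),
            category=("category", "first"),
            subgrid=("subgrid", "first"),
            signal=("signal", "mean"),
        )
        .reset_index()
    )

    # stage 3: sample totals -> mean total
    totals = averaged.groupby("sample_id")["signal"].transform("sum")
    mean_total = averaged.groupby("sample_id")["signal"].sum().mean()
    factor = np.ones(len(averaged))
    ok = totals.to_numpy() != 0
    factor[ok] = mean_total / totals.to_numpy()[ok]
    if not ok.all():
        for sample in averaged.loc[~ok, "sample_id"].unique():
            logger.warning(
                "sample %s has zero total intensity; left unscaled", sample
            )
    averaged["signal"] = averaged["signal"] * factor
    return averaged


def filter_genes_and_probes(
    records: pd.DataFrame, designed_probe_counts: Mapping[str, int]
) -> pd.DataFrame:
    """Apply the detection filters to normalized records.

    A probe is retained only if detected in >= 2 samples. A gene is then
    retained iff its detected probe count is >= 2 and covers >= 33.3% of
    its designed probes. The probe rule runs first so the combined filter
    is idempotent. "Detected" means present in the (QC-filtered) records.
    """
    present = set(records["gene_id"].unique())
    missing = present - set(designed_probe_counts)
    if missing:
        raise ValueError(
            f"genes absent from designed_probe_counts: {sorted(missing)[:5]}"
        )

    probe_samples = records.groupby("probe_id")["sample_id"].nunique()
    good_probes = probe_samples.index[probe_samples >= PROBE_MIN_REPLICATES]
    work = records[records["probe_id"].isin(good_probes)]

    detected = work.groupby("gene_id")["probe_id"].nunique()
    genes = []
    for gene, n_det in detected.items():
        frac = n_det / designed_probe_counts[gene]
        if n_det >= GENE_MIN_PROBES and frac >= GENE_PROBE_FRACTION - 1e-9:
            genes.append(gene)
    return work[work["gene_id"].isin(genes)].reset_index(drop=True)


def rescale_log_transform(
    records: pd.DataFrame,
    designed_probe_counts: Mapping[str, int] | None = None,
) -> GeneSignalMatrix:
    """Rescale per-sample relative abundances and apply ln(x + 1).

    Per sample, each probe's relative abundance (signal / sample total) is
    multiplied by the across-sample mean of the totals; the stored value
    is ln(rescaled + 1). Gene values are means over the gene's retained
    probes. Undetected probes contribute 0.
    """
    if records.empty:
        raise ValueError("no probe records to rescale")
    probe_matrix = records.pivot_table(
        index="probe_id", columns="sample_id", values="signal", fill_value=0.0
    )
    sums = probe_matrix.sum(axis=0)
    zero = sums.index[sums == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total signal: {list(zero)}")
    mean_of_sums = float(sums.mean())
    linear = probe_matrix / sums * mean_of_sums
    logged = np.log1p(linear)

    probe_meta = (
        records[["probe_id", "gene_id", "category"]]
        .drop_duplicates("probe_id")
        .set_index("probe_id")
        .reindex(probe_matrix.index)
    )
    gene_linear = linear.groupby(probe_meta["gene_id"]).mean()
    gene_logged = logged.groupby(probe_meta["gene_id"]).mean()
    categories = (
        records[["gene_id", "category"]]
        .drop_duplicates("gene_id")
        .set_index("gene_id")["category"]
        .reindex(gene_logged.index)
    )
    return GeneSignalMatrix(
        values=gene_logged,
        values_linear=gene_linear,
        categories=categories,
        probe_values=logged,
        probe_values_linear=linear,
        probe_genes=probe_meta["gene_id"],
        probe_categories=probe_meta["category"],
        designed_probe_counts=(
            dict(designed_probe_counts) if designed_probe_counts else None
        ),
    )


def preprocess_pipeline(
    records: pd.DataFrame,
    designed_probe_counts: Mapping[str, int],
    snr_mode: Literal["subtract", "ratio"] = "subtract",
) -> GeneSignalMatrix:
    """Full chain: QC -> normalize -> detection filters -> rescale/log."""
    qc = qc_filter_probes(records, snr_mode=snr_mode)
    norm = normalize(qc)
    filtered = filter_genes_and_probes(norm, designed_probe_counts)
    if filtered.empty:
        raise ValueError("no probes survive the detection filters")
    return rescale_log_transform(filtered, designed_probe_counts)


def load_probe_table(path) -> pd.DataFrame:
    """Read a tab-delimited probe table, validating columns and dtypes.

    Errors name the offending 1-based file line (header = line 1).
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(PROBE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"probe table missing column(s): {sorted(missing)}")
    table = table[list(PROBE_COLUMNS)]
    for col, kind in _NUMERIC.items():
        converted = pd.to_numeric(table[col], errors="coerce")
        bad = converted.isna() & table[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise ValueError(
                f"non-numeric value {table.loc[bad.idxmax(), col]!r} in column "
                f"{col!r} at line {line}"
            )
        if converted.isna().any():
            line = int(converted.isna().idxmax()) + 2
            raise ValueError(f"missing value in column {col!r} at line {line}")
        table[col] = converted.astype(kind)
    return table


def write_probe_table(records: pd.DataFrame, path) -> None:
    records[list(PROBE_COLUMNS)].to_csv(path, sep="\t", index=False)


def load_designed_counts(path) -> dict[str, int]:
    """Read a two-column TSV of gene_id and designed probe count."""
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = {"gene_id", "designed_probes"} - set(table.columns)
    if missing:
        raise ValueError(f"designed-counts table missing: {sorted(missing)}")
    return dict(zip(table["gene_id"], table["designed_probes"].astype(int)))
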