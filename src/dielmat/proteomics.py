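"""Post-search SIP-metaproteomics: SIPPER score filtering and rollups.

SIPPER assigns each peptide-spectrum group six scores describing how well
its isotopic envelope fits a 13C-enriched model.  This module consumes
those score tables (envelope extraction and scoring are upstream and out of
scope), flags labeled peptides with the published "tight" cutoffs
(fit score labeled <= 0.8, I score <= 0.6, sum of ratios >= 0, contig
score >= 0, percent incorporation >= 0.5, percent peptide >= 0.5; boundary
equality passes), rolls labeled/unlabeled peptides up to proteins and to
cyanobacterial vs non-cyanobacterial taxon pools with optional
spectral-count weighting, and builds KEGG-pathway relative-abundance
matrices with square-root transformation for heatmap rendering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd

from .errors import SchemaError

logger = logging.getLogger(__name__)

SCORE_COLUMNS = [
    "fit_score_labeled",
    "i_score",
    "sum_of_ratios",
    "contig_score",
    "percent_incorporation",
    "percent_peptide",
]

PEPTIDE_COLUMNS = ["peptide_id", "protein_id", "timepoint",
                   "incubation", "spectral_count"] + SCORE_COLUMNS

TAXON_BINS = ("cyanobacterial", "non_cyanobacterial")


@dataclass(frozen=True)
class FilterConfig:
    """SIPPER labeling cutoffs; defaults are the tight-filtering values
    calibrated for a false-positive rate near 5%."""

    max_fit_score_labeled: float = 0.8
    max_i_score: float = 0.6
    min_sum_of_ratios: float = 0.0
    min_contig_score: float = 0.0
    min_percent_incorporation: float = 0.5
    min_percent_peptide: float = 0.5

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            if not np.isfinite(getattr(self, f.name)):
                raise SchemaError(f"threshold {f.name} must be finite")


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required columns: {missing}")


def apply_sipper_filters(records: pd.DataFrame,
                         cfg: FilterConfig = FilterConfig()) -> pd.DataFrame:
    """Flag labeled peptides; returns a copy with a boolean ``labeled``.

    A peptide is labeled iff all six score criteria hold, with equality at
    a cutoff passing.  Rows with any missing score are excluded from the
    output (logged), since no call can be made for them.
    """
    if records.empty:
        logger.warning("empty peptide table; nothing to filter")
        out = records.copy()
        out["labeled"] = pd.Series(dtype=bool)
        return out
    _require_columns(records, SCORE_COLUMNS, "peptide table")
    complete = records[SCORE_COLUMNS].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("excluding %d peptide records with missing scores",
                    n_dropped)
    out = records.loc[complete].copy()
    out["labeled"] = (
        (out["fit_score_labeled"] <= cfg.max_fit_score_labeled)
        & (out["i_score"] <= cfg.max_i_score)
        & (out["sum_of_ratios"] >= cfg.min_sum_of_ratios)
        & (out["contig_score"] >= cfg.min_contig_score)
        & (out["percent_incorporation"] >= cfg.min_percent_incorporation)
        & (out["percent_peptide"] >= cfg.min_percent_peptide)
    )
    return out


def attach_taxon_bins(records: pd.DataFrame,
                      taxon_map: pd.DataFrame) -> pd.DataFrame:
    """Join a protein_id -> taxon_bin map onto a peptide table."""
    _require_columns(taxon_map, ["protein_id", "taxon_bin"], "taxon map")
    out = records.merge(taxon_map[["protein_id", "taxon_bin"]],
                        on="protein_id", how="left")
    unmapped = out["taxon_bin"].isna()
    if unmapped.any():
        logger.warning("%d peptides map to no taxon bin; labeled "
                       "'unassigned'", int(unmapped.sum()))
        out.loc[unmapped, "taxon_bin"] = "unassigned"
    return out


def summarize_labeled_proteins(
    records: pd.DataFrame,
    by_taxon: bool = True,
    weight_by_spectra: bool = False,
) -> pd.DataFrame:
    """Labeled-protein counts and relative abundance per condition.

    A protein counts as labeled when at least one of its peptides is
    labeled.  Relative abundance is labeled proteins / total observed
    proteins within each (timepoint, incubation[, taxon_bin]) group — the
    per-column denominator used for reporting.  With
    ``weight_by_spectra=True`` an additional column gives the
    spectral-count-weighted labeled fraction of the *peptide* distribution
    (each peptide weighted by its spectra abundance), the companion
    statistic to the plain protein count.
    """
    if records.empty:
        cols = ["timepoint", "incubation", "n_proteins",
                "n_labeled_proteins", "relative_abundance"]
        if by_taxon:
            cols.insert(2, "taxon_bin")
        return pd.DataFrame(columns=cols)
    if "labeled" not in records.columns:
        raise SchemaError("run apply_sipper_filters first "
                          "(no 'labeled' column)")
    keys = ["timepoint", "incubation"] + (["taxon_bin"] if by_taxon else [])
    _require_columns(records, keys + ["protein_id", "spectral_count"],
                     "peptide table")
    rows = []
    for key_vals, grp in records.groupby(keys, sort=True):
        per_protein = grp.groupby("protein_id")["labeled"].any()
        row = dict(zip(keys, key_vals if isinstance(key_vals, tuple)
                       else (key_vals,)))
        row["n_proteins"] = int(per_protein.size)
        row["n_labeled_proteins"] = int(per_protein.sum())
        row["relative_abundance"] = (row["n_labeled_proteins"]
                                     / row["n_proteins"])
        if weight_by_spectra:
            w = grp["spectral_count"].to_numpy(dtype=float)
            lab = grp["labeled"].to_numpy(dtype=bool)
            row["weighted_labeled_peptide_fraction"] = (
                float(w[lab].sum() / w.sum()) if w.sum() > 0 else 0.0
            )
        rows.append(row)
    return pd.DataFrame(rows)


def pathway_matrix(records: pd.DataFrame,
                   kegg_map: pd.DataFrame) -> pd.DataFrame:
    """Square-root-transformed labeled-protein relative abundance per
    KEGG pathway.

    Rows are pathway ids (plus ``unassigned`` for unmapped proteins);
    columns are (taxon_bin, timepoint, incubation) triples.  The raw value
    is labeled proteins assigned to the pathway divided by total proteins
    observed in that column; a protein assigned to k pathways contributes
    to all k rows, so columns do not sum to the overall labeled fraction.
    Matrix values are sqrt(raw), the variance-stabilizing scale used for
    heatmaps; zeros mean no labeled protein hit the pathway.
    """
    if "labeled" not in records.columns:
        raise SchemaError("run apply_sipper_filters first "
                          "(no 'labeled' column)")
    _require_columns(records, ["taxon_bin"], "peptide table")
    _require_columns(kegg_map, ["protein_id", "pathway_id"], "KEGG map")
    keys = ["taxon_bin", "timepoint", "incubation"]

    pathways = sorted(kegg_map["pathway_id"].unique())
    mapped = set(kegg_map["protein_id"])
    if not set(records["protein_id"]) <= mapped:
        pathways = pathways + ["unassigned"]

    cols = {}
    for key_vals, grp in records.groupby(keys, sort=True):
        per_protein = grp.groupby("protein_id")["labeled"].any()
        n_total = per_protein.size
        labeled_proteins = per_protein[per_protein].index
        assignments = kegg_map[kegg_map["protein_id"]
                               .isin(labeled_proteins)]
        counts = assignments.groupby("pathway_id")["protein_id"].nunique()
        n_unassigned = sum(p not in mapped for p in labeled_proteins)
        raw = pd.Series(0.0, index=pathways)
        raw.loc[counts.index] = counts / n_total
        if "unassigned" in raw.index:
            raw.loc["unassigned"] = n_unassigned / n_total
        cols[key_vals] = np.sqrt(raw)
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=keys)
    out.index.name = "pathway_id"
    return out
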