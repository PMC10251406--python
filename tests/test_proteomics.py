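"""SIPPER score filtering, protein/taxon rollups and pathway matrices."""

import numpy as np
import pandas as pd
import pytest

import dielmat as dm
from dielmat import proteomics as sip
from dielmat import simulate as sim
from dielmat.errors import SchemaError

CUTOFFS = dict(fit_score_labeled=0.8, i_score=0.6, sum_of_ratios=0.0,
               contig_score=0.0, percent_incorporation=0.5,
               percent_peptide=0.5)


def random_records(rng, n=1000):
    """Score table spanning both sides of every cutoff, plus exact-boundary
    records."""
    df = pd.DataFrame({
        "peptide_id": [f"pep{i}" for i in range(n)],
        "protein_id": [f"prot{i % 50}" for i in range(n)],
        "timepoint": 24.0,
        "incubation": "bicarbonate",
        "spectral_count": rng.integers(1, 30, n),
        "fit_score_labeled": rng.uniform(0, 1.6, n),
        "i_score": rng.uniform(0, 1.2, n),
        "sum_of_ratios": rng.uniform(-2, 5, n),
        "contig_score": rng.uniform(-2, 10, n),
        "percent_incorporation": rng.uniform(0, 2, n),
        "percent_peptide": rng.uniform(0, 2, n),
    })
    # force some records to sit exactly on every boundary
    for col, cut in CUTOFFS.items():
        df.loc[df.index[:20], col] = cut
    return df


def brute_force_labeled(row):
    return (row["fit_score_labeled"] <= 0.8 and row["i_score"] <= 0.6
            and row["sum_of_ratios"] >= 0 and row["contig_score"] >= 0
            and row["percent_incorporation"] >= 0.5
            and row["percent_peptide"] >= 0.5)


class TestFilters:
    def test_matches_brute_force_predicate(self, rng):
        df = random_records(rng, 1000)
        flagged = dm.apply_sipper_filters(df)
        expected = df.apply(brute_force_labeled, axis=1)
        assert (flagged["labeled"].to_numpy()
                == expected.to_numpy()).all()

    def test_all_boundary_record_passes(self):
        row = {"peptide_id": "p", "protein_id": "pr", "timepoint": 0,
               "incubation": "b", "spectral_count": 1, **CUTOFFS}
        flagged = dm.apply_sipper_filters(pd.DataFrame([row]))
        assert flagged["labeled"].iloc[0]

    def test_just_over_fit_score_fails(self):
        row = {"peptide_id": "p", "protein_id": "pr", "timepoint": 0,
               "incubation": "b", "spectral_count": 1,
               **{**CUTOFFS, "fit_score_labeled": 0.81}}
        assert not dm.apply_sipper_filters(
            pd.DataFrame([row]))["labeled"].iloc[0]

    def test_idempotent(self, rng):
        df = random_records(rng, 200)
        once = dm.apply_sipper_filters(df)
        twice = dm.apply_sipper_filters(once)
        assert (once["labeled"].to_numpy()
                == twice["labeled"].to_numpy()).all()

    def test_loosening_any_threshold_is_monotone(self, rng):
        df = random_records(rng, 500)
        base = int(dm.apply_sipper_filters(df)["labeled"].sum())
        looser = [
            dm.FilterConfig(max_fit_score_labeled=1.2),
            dm.FilterConfig(max_i_score=1.0),
            dm.FilterConfig(min_sum_of_ratios=-2.0),
            dm.FilterConfig(min_contig_score=-2.0),
            dm.FilterConfig(min_percent_incorporation=0.0),
            dm.FilterConfig(min_percent_peptide=0.0),
        ]
        for cfg in looser:
            assert int(dm.apply_sipper_filters(df, cfg)["labeled"].sum()) \
                >= base

    def test_missing_scores_excluded(self, rng):
        df = random_records(rng, 10)
        df.loc[0, "i_score"] = np.nan
        flagged = dm.apply_sipper_filters(df)
        assert len(flagged) == 9

    def test_empty_table(self):
        out = dm.apply_sipper_filters(pd.DataFrame())
        assert out.empty and "labeled" in out.columns


def small_table(labeled_rows):
    """Two-peptide protein helper: labeled_rows marks which peptides pass."""
    rows = []
    for i, lab in enumerate(labeled_rows):
        scores = {k: v for k, v in CUTOFFS.items()}
        if not lab:
            scores["fit_score_labeled"] = 1.5
        rows.append({"peptide_id": f"p{i}", "protein_id": "prot1",
                     "timepoint": 24.0, "incubation": "glucose",
                     "spectral_count": 5, "taxon_bin": "cyanobacterial",
                     **scores})
    return dm.apply_sipper_filters(pd.DataFrame(rows))


class TestSummaries:
    def test_one_labeled_peptide_labels_the_protein(self):
        out = dm.summarize_labeled_proteins(small_table([True, False]))
        assert out["n_labeled_proteins"].iloc[0] == 1
        assert out["relative_abundance"].iloc[0] == 1.0

    def test_no_labeled_peptides(self):
        out = dm.summarize_labeled_proteins(small_table([False, False]))
        assert out["relative_abundance"].iloc[0] == 0.0

    def test_recovers_planted_fraction(self):
        fractions = {("bicarbonate", 24.0, b): f
                     for b, f in zip(sip.TAXON_BINS, (0.056, 0.056))}
        peptides, taxon_map, _, truth = sim.emit_peptide_tables(
            fractions, n_proteins_per_bin=1000, seed=11)
        flagged = dm.attach_taxon_bins(dm.apply_sipper_filters(peptides),
                                       taxon_map)
        out = dm.summarize_labeled_proteins(flagged, by_taxon=False)
        est = out["relative_abundance"].iloc[0]
        # binomial 95% interval around the planted truth at n=2000
        n, p = 2000, 0.056
        half = 1.96 * np.sqrt(p * (1 - p) / n)
        assert abs(est - p) <= half

    def test_rollup_conservation(self):
        peptides, taxon_map, _, _ = sim.emit_peptide_tables(
            n_proteins_per_bin=60, seed=5)
        flagged = dm.attach_taxon_bins(dm.apply_sipper_filters(peptides),
                                       taxon_map)
        by_bin = dm.summarize_labeled_proteins(flagged, by_taxon=True)
        overall = dm.summarize_labeled_proteins(flagged, by_taxon=False)
        merged = by_bin.groupby(["timepoint", "incubation"])[
            "n_labeled_proteins"].sum().reset_index()
        check = merged.merge(overall, on=["timepoint", "incubation"])
        assert (check["n_labeled_proteins_x"]
                == check["n_labeled_proteins_y"]).all()

    def test_spectral_weighting_column(self):
        out = dm.summarize_labeled_proteins(small_table([True, False]),
                                            weight_by_spectra=True)
        assert out["weighted_labeled_peptide_fraction"].iloc[0] == \
            pytest.approx(0.5)

    def test_requires_labeled_flag(self):
        with pytest.raises(SchemaError):
            dm.summarize_labeled_proteins(
                pd.DataFrame({"timepoint": [1], "incubation": ["x"],
                              "taxon_bin": ["cyanobacterial"],
                              "protein_id": ["p"], "spectral_count": [1]}))


class TestPathwayMatrix:
    def test_multi_pathway_protein_counts_in_all_rows(self):
        flagged = small_table([True])
        kegg = pd.DataFrame({"protein_id": ["prot1", "prot1"],
                             "pathway_id": ["Photosynthesis",
                                            "Carbon fixation"]})
        m = dm.pathway_matrix(flagged, kegg)
        col = m.columns[0]
        assert m.loc["Photosynthesis", col] == pytest.approx(1.0)
        assert m.loc["Carbon fixation", col] == pytest.approx(1.0)

    def test_values_are_sqrt_of_raw(self):
        # 1 labeled of 4 proteins in a pathway -> raw 0.25 -> value 0.5
        rows = []
        for i in range(4):
            scores = dict(CUTOFFS)
            if i != 0:
                scores["i_score"] = 1.5
            rows.append({"peptide_id": f"p{i}", "protein_id": f"prot{i}",
                         "timepoint": 24.0, "incubation": "glucose",
                         "spectral_count": 1,
                         "taxon_bin": "cyanobacterial", **scores})
        flagged = dm.apply_sipper_filters(pd.DataFrame(rows))
        kegg = pd.DataFrame({"protein_id": [f"prot{i}" for i in range(4)],
                             "pathway_id": ["Photosynthesis"] * 4})
        m = dm.pathway_matrix(flagged, kegg)
        assert m.loc["Photosynthesis", m.columns[0]] == pytest.approx(0.5)

    def test_unlabeled_column_all_zero(self):
        flagged = small_table([False, False])
        kegg = pd.DataFrame({"protein_id": ["prot1"],
                             "pathway_id": ["Photosynthesis"]})
        m = dm.pathway_matrix(flagged, kegg)
        assert (m.to_numpy() == 0).all()

    def test_unmapped_proteins_get_unassigned_row(self):
        flagged = small_table([True])
        kegg = pd.DataFrame({"protein_id": ["other"],
                             "pathway_id": ["Photosynthesis"]})
        m = dm.pathway_matrix(flagged, kegg)
        assert m.loc["unassigned", m.columns[0]] > 0


class TestGeneratorTruth:
    def test_planted_bin_ordering_recovered(self):
        peptides, taxon_map, _, truth = sim.emit_peptide_tables(
            n_proteins_per_bin=200, seed=9)
        flagged = dm.attach_taxon_bins(dm.apply_sipper_filters(peptides),
                                       taxon_map)
        out = dm.summarize_labeled_proteins(flagged, by_taxon=True)
        piv = out.pivot_table(index=["incubation", "timepoint"],
                              columns="taxon_bin",
                              values="relative_abundance")
        # cyanobacterial pool planted more labeled at every condition
        assert (piv["cyanobacterial"]
                >= piv["non_cyanobacterial"]).all()
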