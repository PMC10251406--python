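"""End-to-end orchestration of the diel-mat tracer analysis.

``run_all`` simulates the reference scenario (three labeled-substrate
incubations plus a dark bicarbonate control), then runs every analysis
stage over the generated tables and writes a report bundle:

* ``replacement_profiles.csv`` — per-spot percent replacement;
* ``partition.csv`` — photic/aphotic split and mean replacement per
  (treatment, timepoint), averaged over replicate profiles;
* ``diel.csv`` — percent of dusk-held tracer lost by dawn, per treatment;
* ``acidwash.csv`` — removed-pool classification and inferred composition;
* ``mid_calls.csv`` / ``mid_excess.csv`` — three-level labeling matrix;
* ``protein_summary.csv`` / ``pathway_matrix.csv`` — SIP-proteomics
  rollups;
* ``summary.json`` — the headline numbers plus truth-recovery checks
  against the generator sidecars.

Every stage is also callable on its own against externally supplied
tables.  Outputs are byte-reproducible for a fixed config and seed.
"""

from __future__ import annotations

import dataclasses
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from . import isotopes as iso
from . import profiles as prof
from . import proteomics as sip
from . import simulate as sim
from .acidwash import AcidWashSample, classify_removed_pool, \
    removed_pool_atom_fraction
from .errors import (DielmatError, UndefinedLossError,
                     UndefinedPartitionError)
from .mid import CallThresholds, call_matrix

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (fully serializable)."""

    seed: int = 0
    control_delta: float = -20.0
    photic_boundary: float | None = None  # None: derive from irradiance
    irradiance_threshold: float = prof.PHOTIC_IRRADIANCE_THRESHOLD
    dusk_h: float = sim.DUSK_H
    dawn_h: float = sim.DAWN_H
    include_dark_control: bool = True
    #: treatments whose dusk uptake sits below this floor (percent) have
    #: their diel loss flagged as noise-floor arithmetic; reporting only,
    #: integrals are never clipped
    reporting_floor_pct: float = 0.05
    n_proteins_per_bin: int = 1000
    call_thresholds: CallThresholds = field(default_factory=CallThresholds)
    filter_config: sip.FilterConfig = field(
        default_factory=sip.FilterConfig)
    sim_overrides: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = dio.read_yaml(path)
        if "call_thresholds" in d:
            d["call_thresholds"] = CallThresholds(**d["call_thresholds"])
        if "filter_config" in d:
            d["filter_config"] = sip.FilterConfig(**d["filter_config"])
        return cls(**d)


def simulate_inputs(inputs_dir: Path, cfg: RunConfig) -> dict:
    """Generate every input table of the reference scenario.

    Child seeds are derived deterministically from ``cfg.seed`` (and kept
    below 2**31) so each table family has an independent stream.
    """
    inputs_dir = Path(inputs_dir)
    substrates = iso.default_substrates()
    child = np.random.SeedSequence(cfg.seed).generate_state(8) % (2 ** 31)
    truth: dict = {"seed": cfg.seed}

    spot_frames = []
    scenarios = [(name, substrates[name], None)
                 for name in sorted(substrates)]
    if cfg.include_dark_control:
        scenarios.append(("bicarbonate", substrates["bicarbonate"],
                          "bicarbonate_dark"))
    spot_truth = {}
    for i, (name, spec, label) in enumerate(scenarios):
        overrides = dict(cfg.sim_overrides)
        if label is not None:
            overrides["peak_irradiance"] = 0.0
        params = sim.MatSimParams(
            substrate=spec, seed=int(child[0] + i) % (2 ** 31),
            control_delta=cfg.control_delta, treatment_label=label,
            **overrides)
        field_ = sim.simulate_replacement_field(params)
        table, t = sim.emit_spot_tables(field_)
        spot_frames.append(table)
        spot_truth[params.treatment] = t
    dio.write_table(pd.concat(spot_frames, ignore_index=True),
                    inputs_dir / "spots.csv")
    truth["spots"] = spot_truth

    # tabulated irradiance-vs-depth profile for the photic boundary
    ref_params = sim.MatSimParams(substrate=substrates["bicarbonate"],
                                  **cfg.sim_overrides)
    z = np.linspace(0.0, 1.0, 101)
    irr = ref_params.peak_irradiance * np.exp(
        -z / ref_params.attenuation_length)
    dio.write_table(
        pd.DataFrame({"normalized_depth": z, "irradiance": irr}),
        inputs_dir / "irradiance.csv")

    intensities, mid_truth = sim.emit_mid_tables(seed=int(child[1]))
    dio.write_table(intensities, inputs_dir / "mid_intensities.csv")
    dio.write_table(mid_truth, inputs_dir / "mid_truth.csv")

    peptides, taxon_map, kegg_map, pep_truth = sim.emit_peptide_tables(
        n_proteins_per_bin=cfg.n_proteins_per_bin, seed=int(child[2]))
    dio.write_table(peptides, inputs_dir / "peptides.csv")
    taxon_map.to_csv(inputs_dir / "taxon_map.tsv", sep="\t", index=False,
                     lineterminator="\n")
    kegg_map.to_csv(inputs_dir / "kegg_map.tsv", sep="\t", index=False,
                    lineterminator="\n")
    dio.write_table(pep_truth, inputs_dir / "peptide_truth.csv")

    acid, acid_truth = sim.emit_acidwash_tables(seed=int(child[3]))
    dio.write_table(acid, inputs_dir / "acidwash.csv")
    dio.write_table(acid_truth, inputs_dir / "acidwash_truth.csv")

    dio.write_json(truth, inputs_dir / "truth.json")
    return truth


def stage_replace(spots: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Per-spot replacement profiles for every profile in a spot table."""
    substrates = iso.default_substrates()
    rows = []
    for profile in dio.spot_table_to_profiles(spots):
        base = profile.treatment.split("_")[0]  # "bicarbonate_dark" -> spec
        if base not in substrates:
            raise DielmatError(f"no substrate spec for treatment "
                               f"{profile.treatment!r}")
        rp = prof.replacement_profile(profile, cfg.control_delta,
                                      substrates[base])
        for z, pct, flag in zip(rp.depths, rp.percent, rp.flags):
            rows.append({
                "profile_id": rp.profile_id, "treatment": rp.treatment,
                "timepoint_h": rp.timepoint_h, "normalized_depth": z,
                "percent_replacement": pct, "flagged": bool(flag),
            })
    return pd.DataFrame(rows)


def _replacement_profiles(df: pd.DataFrame) -> list[prof.ReplacementProfile]:
    out = []
    for pid, grp in df.groupby("profile_id", sort=True):
        grp = grp.sort_values("normalized_depth")
        out.append(prof.ReplacementProfile(
            profile_id=str(pid),
            depths=grp["normalized_depth"].to_numpy(),
            percent=grp["percent_replacement"].to_numpy(),
            flags=grp["flagged"].to_numpy(dtype=bool),
            timepoint_h=float(grp["timepoint_h"].iloc[0]),
            treatment=str(grp["treatment"].iloc[0]),
        ))
    return out


def stage_partition(replacement: pd.DataFrame, boundary: float,
                    cfg: RunConfig) -> pd.DataFrame:
    """Photic partition and mean replacement per (treatment, timepoint).

    Statistics are computed per replicate profile first and then averaged
    across profiles (profiles have unequal spot counts).  Profiles whose
    total integral is not positive (e.g. dark controls at the noise
    floor) contribute NaN fractions and are flagged rather than dropped.
    """
    rows = []
    rps = _replacement_profiles(replacement)
    keyed: dict[tuple, list] = {}
    for rp in rps:
        keyed.setdefault((rp.treatment, rp.timepoint_h), []).append(rp)
    for (treatment, timepoint), group in sorted(keyed.items()):
        fracs, means, flagged = [], [], False
        for rp in group:
            means.append(prof.mean_replacement(rp))
            try:
                part = prof.partition_at_boundary(rp, boundary)
            except UndefinedPartitionError:
                flagged = True
                continue
            if part.flagged:
                flagged = True
            else:
                fracs.append(part.fraction_below)
        mean = prof.combine_profile_means(means)
        fb = float(np.mean(fracs)) if fracs else float("nan")
        rows.append({
            "treatment": treatment, "timepoint_h": timepoint,
            "boundary": boundary, "fraction_below": fb,
            "fraction_above": 1.0 - fb if fracs else float("nan"),
            "mean_replacement_pct": mean.integrated,
            "spot_mean_pct": mean.spot_mean,
            "n_profiles": len(group), "flagged": flagged,
        })
    return pd.DataFrame(rows)


def stage_diel(partition: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Dusk-to-dawn tracer loss per treatment from the partition table."""
    rows = []
    for treatment, grp in partition.groupby("treatment", sort=True):
        grp = grp.set_index("timepoint_h")
        if cfg.dusk_h not in grp.index or cfg.dawn_h not in grp.index:
            logger.warning("%s: dusk/dawn timepoints missing; skipping",
                           treatment)
            continue
        dusk = float(grp.loc[cfg.dusk_h, "mean_replacement_pct"])
        dawn = float(grp.loc[cfg.dawn_h, "mean_replacement_pct"])
        try:
            loss = prof.diel_loss(dusk, dawn)
            flagged = loss < 0 or dusk < cfg.reporting_floor_pct
        except UndefinedLossError:
            loss, flagged = float("nan"), True
        rows.append({
            "treatment": treatment, "dusk_h": cfg.dusk_h,
            "dawn_h": cfg.dawn_h, "uptake_dusk_pct": dusk,
            "uptake_dawn_pct": dawn, "diel_loss_pct": loss,
            "flagged": flagged,
        })
    return pd.DataFrame(rows)


def stage_acidwash(acid: pd.DataFrame) -> pd.DataFrame:
    """Classify each acid-wash pair and invert the mass balance when the
    removed carbon fraction is available."""
    rows = []
    for _, r in acid.iterrows():
        f = r.get("carbon_fraction_removed")
        sample = AcidWashSample(
            sample_id=str(r["sample_id"]),
            delta_pre=float(r["delta_pre"]),
            delta_post=float(r["delta_post"]),
            delta_supernatant=(float(r["delta_supernatant"])
                               if pd.notna(r.get("delta_supernatant"))
                               else None),
            carbon_fraction_removed=(float(f) if pd.notna(f) else None),
        )
        row = {
            "sample_id": sample.sample_id,
            "treatment": r.get("treatment", ""),
            "timepoint_h": r.get("timepoint_h", float("nan")),
            "classification": classify_removed_pool(sample).value,
        }
        if sample.carbon_fraction_removed is not None:
            f_removed = removed_pool_atom_fraction(sample)
            row["removed_atom_fraction"] = f_removed
            row["removed_delta_permil"] = iso.atom_fraction_to_delta(
                f_removed)
        rows.append(row)
    return pd.DataFrame(rows)


def stage_mid(intensities: pd.DataFrame,
              cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    wide, long = call_matrix(intensities, thresholds=cfg.call_thresholds)
    flat = wide.copy()
    flat.columns = [f"{m}_t{t}" for m, t in wide.columns]
    return flat.reset_index(), long


def stage_sip(peptides: pd.DataFrame, taxon_map: pd.DataFrame,
              kegg_map: pd.DataFrame, cfg: RunConfig
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    flagged = sip.apply_sipper_filters(peptides, cfg.filter_config)
    flagged = sip.attach_taxon_bins(flagged, taxon_map)
    by_bin = sip.summarize_labeled_proteins(flagged, by_taxon=True,
                                            weight_by_spectra=True)
    overall = sip.summarize_labeled_proteins(flagged, by_taxon=False)
    overall["taxon_bin"] = "all"
    summary = pd.concat([by_bin, overall], ignore_index=True)
    matrix = sip.pathway_matrix(flagged, kegg_map)
    flat = matrix.copy()
    flat.columns = ["|".join(str(v) for v in c) for c in matrix.columns]
    return summary, flat.reset_index()


def _summarize(results: dict, truth: dict, cfg: RunConfig,
               boundary: float) -> dict:
    """Headline numbers plus truth-recovery checks for the run log."""
    partition: pd.DataFrame = results["partition"]
    diel: pd.DataFrame = results["diel"]
    summary: dict = {"boundary": boundary, "seed": cfg.seed}
    final_t = partition["timepoint_h"].max()
    for treatment, grp in partition.groupby("treatment"):
        last = grp[grp["timepoint_h"] == final_t].iloc[0]
        summary[f"mean_replacement_{treatment}_pct"] = float(
            last["mean_replacement_pct"])
        if np.isfinite(last["fraction_below"]):
            summary[f"fraction_below_{treatment}_pct"] = float(
                100.0 * last["fraction_below"])
        true_mean = truth["spots"][treatment][
            "true_mean_replacement_pct"][-1]
        summary[f"true_mean_replacement_{treatment}_pct"] = float(true_mean)
    for _, r in diel.iterrows():
        if np.isfinite(r["diel_loss_pct"]) \
                and r["uptake_dusk_pct"] >= cfg.reporting_floor_pct:
            summary[f"diel_loss_{r['treatment']}_pct"] = float(
                r["diel_loss_pct"])
    return summary


def run_all(outdir, seed: int | None = None,
            cfg: RunConfig | None = None) -> dict:
    """Simulate the reference scenario and run every stage.

    Returns a dict of output DataFrames; writes the report bundle under
    ``outdir/inputs`` and ``outdir/results``.  Partial results are removed
    if any stage fails.
    """
    cfg = cfg or RunConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    outdir = Path(outdir)
    inputs_dir = outdir / "inputs"
    results_dir = outdir / "results"
    results_dir.mkdir(parents=True, exist_ok=True)
    try:
        truth = simulate_inputs(inputs_dir, cfg)

        spots = dio.read_spot_table(inputs_dir / "spots.csv")
        replacement = stage_replace(spots, cfg)
        dio.write_table(replacement,
                        results_dir / "replacement_profiles.csv")
        logger.info("replace: %d spots in, %d rows out",
                    len(spots), len(replacement))

        if cfg.photic_boundary is not None:
            boundary = cfg.photic_boundary
        else:
            irr = pd.read_csv(inputs_dir / "irradiance.csv")
            boundary = prof.boundary_from_irradiance(
                irr["normalized_depth"], irr["irradiance"],
                cfg.irradiance_threshold)
        partition = stage_partition(replacement, boundary, cfg)
        dio.write_table(partition, results_dir / "partition.csv")

        diel = stage_diel(partition, cfg)
        dio.write_table(diel, results_dir / "diel.csv")

        acid = dio.read_acidwash_table(inputs_dir / "acidwash.csv")
        acid_out = stage_acidwash(acid)
        dio.write_table(acid_out, results_dir / "acidwash.csv")

        intensities = dio.read_intensity_table(
            inputs_dir / "mid_intensities.csv")
        calls, excess = stage_mid(intensities, cfg)
        dio.write_table(calls, results_dir / "mid_calls.csv")
        dio.write_table(excess, results_dir / "mid_excess.csv")

        peptides = dio.read_peptide_table(inputs_dir / "peptides.csv")
        taxon_map = dio.read_map_table(inputs_dir / "taxon_map.tsv",
                                       "taxon_bin")
        kegg_map = dio.read_map_table(inputs_dir / "kegg_map.tsv",
                                      "pathway_id")
        protein_summary, pathway = stage_sip(peptides, taxon_map,
                                             kegg_map, cfg)
        dio.write_table(protein_summary,
                        results_dir / "protein_summary.csv")
        dio.write_table(pathway, results_dir / "pathway_matrix.csv")

        results = {
            "replacement": replacement, "partition": partition,
            "diel": diel, "acidwash": acid_out, "mid_calls": calls,
            "mid_excess": excess, "protein_summary": protein_summary,
            "pathway_matrix": pathway,
        }
        summary = _summarize(results, truth, cfg, boundary)
        dio.write_json(summary, results_dir / "summary.json")
        dio.write_json({"config": cfg.to_dict(),
                        "rows": {k: len(v) for k, v in results.items()}},
                       results_dir / "run_log.json")
        results["summary"] = summary
        return results
    except Exception:
        shutil.rmtree(results_dir, ignore_errors=True)
        raise
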