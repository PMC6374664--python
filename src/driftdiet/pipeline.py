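"""Run configuration, orchestration and report rendering.

``RunConfig`` carries every tunable stage parameter with the study
defaults (rarefaction depth 1950, prey-read threshold 20, identity
0.95, clustering at 2 edits, 99,999 permutations, availability zero
floor 0.001, overlap threshold 0.6) and a mandatory seed.
``run_pipeline`` wires the stages end to end on synthetic fixtures and
writes every intermediate table plus a manifest; ``render_report``
turns a result bundle into a human-readable summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import driftdiet
from driftdiet import bias as bias_mod
from driftdiet import drift as drift_mod
from driftdiet import metrics, seqproc, synthetic
from driftdiet.containers import DietMatrix, SampleTable
from driftdiet.taxonomy import EsuTaxonomy

__all__ = ["RunConfig", "run_pipeline", "render_report",
           "load_diet_matrix", "save_diet_matrix"]


@dataclass
class RunConfig:
    """All stage parameters for one reproducible run."""

    seed: int = 0
    output_dir: str = "driftdiet_run"
    depth: int = 1950
    min_prey_reads: int = 20
    min_identity: float = 0.95
    max_diff: int = 2
    max_trimmed_length: int = 175
    homopolymer_min: int = 8
    n_perm: int = 99_999
    zero_floor: float = 0.001
    overlap_threshold: float = 0.6
    pooling: str = "sum_counts"
    community: dict = field(default_factory=dict)  # CommunityConfig overrides

    def __post_init__(self) -> None:
        for name in ("depth", "min_prey_reads", "max_diff", "n_perm",
                     "max_trimmed_length", "homopolymer_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if self.zero_floor <= 0:
            raise ValueError("zero_floor must be positive")
        if self.overlap_threshold <= 0:
            raise ValueError("overlap_threshold must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a YAML config; keyword overrides win over file values."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_jsonable(self) -> dict:
        return dataclasses.asdict(self)


def save_diet_matrix(diet: DietMatrix, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    diet.proportions.to_csv(out / "diet_proportions.tsv", sep="\t")
    diet.prey_reads.rename("prey_reads").to_csv(out / "prey_reads.tsv", sep="\t")
    diet.metadata.to_csv(out / "diet_metadata.tsv", sep="\t")


def load_diet_matrix(indir: str | Path) -> DietMatrix:
    ind = Path(indir)
    props = pd.read_csv(ind / "diet_proportions.tsv", sep="\t", index_col=0)
    reads = pd.read_csv(ind / "prey_reads.tsv", sep="\t", index_col=0)["prey_reads"]
    meta = pd.read_csv(ind / "diet_metadata.tsv", sep="\t", index_col=0)
    return DietMatrix(props, reads, meta)


def _digest(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Simulate -> process -> bias -> drift -> metrics, with manifest.

    All randomness derives from ``config.seed``; rerunning with an
    identical config is bit-identical (the manifest digest is stable).
    Outputs are written under ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        community = synthetic.CommunityConfig(seed=config.seed,
                                              rarefaction_depth=config.depth,
                                              **config.community)
        references, taxonomy = synthetic.generate_reference_db(community)
        sim = synthetic.simulate_diet_samples(community, taxonomy, references)
        survey = synthetic.simulate_drift_survey(community)

        stage = "process"
        result = seqproc.process_pipeline(
            sim.table, sim.otu_sequences, references, taxonomy,
            depth=config.depth, min_prey_reads=config.min_prey_reads,
            max_trimmed_length=config.max_trimmed_length,
            homopolymer_min=config.homopolymer_min, max_diff=config.max_diff,
            min_identity=config.min_identity, seed=config.seed)
        diet = result["diet_matrix"]
        save_diet_matrix(diet, out)
        result["exclusion_log"].to_csv(out / "exclusions.tsv", sep="\t",
                                       index=False)

        stage = "bias"
        prey_esus = [e for e in taxonomy.esus
                     if e in taxonomy.bilaterian_esus]
        mock_rng = synthetic._substream(config.seed, "mock")
        # roughly equal biomass per family, as in a tissue homogenate
        biomass = pd.Series(
            mock_rng.dirichlet(np.full(len(prey_esus), 50.0)), index=prey_esus)
        mock = synthetic.simulate_mock_homogenate(
            biomass, sim.bias[prey_esus], depth=9450, seed=mock_rng)
        rcf = bias_mod.compute_rcf(mock)
        rcf.to_csv(out / "rcf.tsv", sep="\t", index=False)
        correlation = bias_mod.biomass_sequence_correlation(mock)

        stage = "drift"
        survey["biomass_g"] = drift_mod.estimate_catch_biomass(
            survey["count"], survey["individual_dry_mass_mg"],
            survey["subsample_fraction"])
        nightly = drift_mod.aggregate_biomass_to_esu(survey)
        periods = survey.drop_duplicates("night").set_index("night")["period"]
        period_means = drift_mod.period_average_biomass(nightly, periods)
        nightly.to_csv(out / "nightly_esu_biomass.tsv", sep="\t")
        period_means.to_csv(out / "period_biomass.tsv", sep="\t")

        stage = "metrics"
        overlap = metrics.overlap_matrices(diet, pooling=config.pooling)
        test = None
        if len(overlap.paired_delta) >= 2:
            pairs = list(overlap.paired_delta.index)
            first, second = "drift", "postdrift"
            a_first = [overlap.alpha[first].loc[a, b] for a, b in pairs]
            a_second = [overlap.alpha[second].loc[a, b] for a, b in pairs]
            test = metrics.paired_sign_flip_test(
                a_first, a_second, n_perm=config.n_perm, seed=config.seed)
            overlap.mean_delta = test.mean_delta
            overlap.p_value = test.p_value
            overlap.n_permutations = test.n_permutations
        for period, mat in overlap.alpha.items():
            mat.to_csv(out / f"overlap_{period}.tsv", sep="\t")
        overlap.paired_delta.rename("delta_alpha").to_csv(
            out / "overlap_delta.tsv", sep="\t")

        surveyed = [e for e in nightly.columns if e in diet.esus]
        availability = nightly.apply(
            lambda r: drift_mod.availability_proportions(
                r[surveyed], zero_floor=config.zero_floor), axis=1)
        # map sampling day labels to survey nights (fish sampled the
        # morning after each net night)
        date_to_night = {}
        for night, period in periods.items():
            idx = night.rsplit("_", 1)[-1]
            date_to_night[f"{period}_day_{idx}"] = night
        selectivity = metrics.selectivity_by_day(
            diet, availability, surveyed, date_to_night=date_to_night)
        selectivity.to_csv(out / "selectivity.tsv", sep="\t", index=False)
    except Exception:
        (out / "FAILED_STAGE").write_text(stage)
        raise

    bundle = {
        "config": config,
        "diet_matrix": diet,
        "exclusion_log": result["exclusion_log"],
        "filter_report": result["filter_report"],
        "rcf": rcf,
        "correlation": correlation,
        "period_biomass": period_means,
        "overlap": overlap,
        "test": test,
        "selectivity": selectivity,
        "true_bias": sim.bias,
    }
    manifest = {
        "config": config.to_jsonable(),
        "seed": config.seed,
        "version": driftdiet.__version__,
        "stage_rows": {
            "samples_simulated": int(len(sim.table.samples)),
            "samples_retained": int(len(diet.samples)),
            "samples_excluded": int(len(result["exclusion_log"])),
            "otus": int(result["clustering"].n_otus),
            "rcf_families": int(len(rcf)),
            "overlap_pairs": int(len(overlap.paired_delta)),
            "selectivity_rows": int(len(selectivity)),
        },
    }
    manifest["digest"] = _digest(manifest)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    bundle["manifest"] = manifest
    return bundle


def render_report(bundle: dict) -> str:
    """Readable summary of a pipeline run."""
    lines = ["driftdiet run summary", "====================="]
    cfg: RunConfig = bundle["config"]
    lines.append(f"seed={cfg.seed} depth={cfg.depth} "
                 f"min_prey_reads={cfg.min_prey_reads}")
    log = bundle["exclusion_log"]
    lines.append("")
    lines.append("Exclusions by reason:")
    if len(log):
        for reason, n in log["reason"].value_counts().items():
            lines.append(f"  {reason}: {n}")
    else:
        lines.append("  none")
    fr = bundle["filter_report"]
    lines.append(f"Screened sequences: too_long={fr.too_long} "
                 f"homopolymer={fr.homopolymer} singleton={fr.singleton}")
    lines.append("")
    lines.append("Relative correction factors:")
    for _, row in bundle["rcf"].iterrows():
        tag = " (over)" if row["overrepresented"] else " (under)"
        val = "undefined" if pd.isna(row["rcf"]) else f"{row['rcf']:.3f}"
        lines.append(f"  {row['family']}: {val}{tag}")
    corr = bundle["correlation"]
    if not corr.get("undefined"):
        lines.append(f"Biomass-sequence correlation: r={corr['r']:.3f} "
                     f"R2={corr['r_squared']:.3f} p={corr['p_value']:.3g}")
    overlap = bundle["overlap"]
    for period, mat in overlap.alpha.items():
        lines.append("")
        lines.append(f"Schoener overlap, {period} period:")
        pairs = overlap.substantial_pairs(period, cfg.overlap_threshold)
        n_species = mat.notna().any(axis=1).sum()
        if n_species < 2:
            lines.append("  (fewer than 2 species; no overlap computed)")
            continue
        if pairs:
            for a, b, v in pairs:
                lines.append(f"  {a} - {b}: alpha={v:.2f} substantial")
        else:
            lines.append(f"  no pair above {cfg.overlap_threshold}")
    if bundle.get("test") is not None:
        t = bundle["test"]
        lines.append("")
        lines.append(f"Paired sign-flip test: mean delta alpha="
                     f"{t.mean_delta:.3f}, p={t.p_value:.4g} "
                     f"({t.n_permutations} permutations, {t.n_pairs} pairs)")
    sel = bundle["selectivity"]
    if len(sel):
        lines.append("")
        lines.append("Strongest selection (Chesson epsilon):")
        top = sel.reindex(sel["chesson_epsilon"].abs()
                          .sort_values(ascending=False).index).head(3)
        for _, row in top.iterrows():
            lines.append(f"  {row['predator_species']} {row['date']} "
                         f"{row['esu']}: eps={row['chesson_epsilon']:.2f}")
    return "\n".join(lines) + "\n"
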