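"""End-to-end orchestration: validate -> weights -> matrices -> descriptives
-> regression, from a single config, with a hashed artifact manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .descriptives import (
    contact_totals,
    distance_mobility_tables,
    participant_summaries,
    reporting_method_comparison,
    setting_proportions,
    weighted_median_iqr,
)
from .matrices import setting_stratified_matrices
from .raking import MarginSpec, rake_weights
from .regression import fit_nb_model
from .schemes import MATRIX_SCHEME
from .survey import PopulationTable, Survey, load_survey, write_survey
from .synthetic import GeneratorConfig, generate_survey
from .validation import SamplingDesign, validate_survey

__all__ = ["PipelineConfig", "run_pipeline", "load_population_csv", "write_population_csv"]

_STAGES = ("validate", "weights", "matrices", "describe", "regress")


@dataclass
class PipelineConfig:
    """One config for a full run.

    Exactly one of ``input_paths`` (dict with participants/contacts/
    supplementary CSVs plus a population CSV) or ``simulate``
    (a :class:`GeneratorConfig`) must be given.
    """

    out_dir: str | Path = "out"
    input_paths: dict[str, str] | None = None
    simulate: GeneratorConfig | None = None
    margin_targets: dict[str, dict[str, float]] | None = None
    seed: int = 0
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in _STAGES}
    )
    run_anova: bool = False
    attribution: str = "each"

    def __post_init__(self) -> None:
        if (self.input_paths is None) == (self.simulate is None):
            raise ValueError("give exactly one of input_paths or simulate")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = GeneratorConfig(**raw["simulate"])
        return cls(**raw)


def write_population_csv(pops: dict[str, PopulationTable], path: Path) -> None:
    rows = []
    for stratum, tab in sorted(pops.items()):
        for b, n in enumerate(tab.N):
            rows.append(
                {"stratum": stratum, "band": tab.scheme.labels[b], "N": int(n)}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_population_csv(path: str | Path) -> dict[str, PopulationTable]:
    df = pd.read_csv(path)
    out = {}
    for stratum, grp in df.groupby("stratum"):
        order = {lab: i for i, lab in enumerate(MATRIX_SCHEME.labels)}
        grp = grp.sort_values("band", key=lambda s: s.map(order))
        out[stratum] = PopulationTable(
            MATRIX_SCHEME, stratum, grp["N"].to_numpy(dtype=float)
        )
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage in order; returns the artifact manifest.

    Stages whose prerequisites are disabled are auto-disabled with a warning
    in the log. The manifest lists every file written, with content hashes,
    so two runs under the same seed and config are hash-identical.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    stages = {s: config.stages.get(s, True) for s in _STAGES}

    # dependency contract: matrices/describe/regress need weights
    if not stages["weights"]:
        for dep in ("matrices", "describe", "regress"):
            if stages[dep]:
                log.append(f"WARNING: stage {dep} disabled (requires weights)")
                stages[dep] = False

    # --- inputs ------------------------------------------------------------
    if config.simulate is not None:
        gen = config.simulate.replace(seed=config.seed)
        survey, truth = generate_survey(gen)
        pops = truth.population
        write_survey(survey, out / "survey")
        write_population_csv(pops, out / "survey" / "population.csv")
        margin_targets = config.margin_targets or truth.weights_target_margins
        log.append(
            f"INFO: simulated survey n={survey.n_participants}, "
            f"diary contacts={survey.n_diary_contacts}"
        )
    else:
        paths = config.input_paths
        survey = load_survey(
            paths["participants"], paths["contacts"], paths.get("supplementary")
        )
        pops = load_population_csv(paths["population"])
        if "all" not in pops and {"urban", "rural"} <= set(pops):
            pops["all"] = pops["urban"].combined_with(pops["rural"])
        margin_targets = config.margin_targets
        if survey.parse_issues:
            log.append(f"WARNING: {len(survey.parse_issues)} unparseable rows")
        log.append(f"INFO: loaded survey n={survey.n_participants}")

    # --- validate ----------------------------------------------------------
    if stages["validate"]:
        report = validate_survey(survey, SamplingDesign())
        report.quota_table.to_csv(out / "quota_table.csv", index=False)
        log.append(
            f"INFO: validation errors={len(report.errors)} "
            f"warnings={len(report.warnings)}"
        )
        if report.errors:
            raise RuntimeError(
                f"validation failed with {len(report.errors)} error(s); "
                "see quota_table.csv and log"
            )

    # --- weights -----------------------------------------------------------
    weights = None
    if stages["weights"]:
        if not margin_targets:
            raise ValueError("weights stage needs margin_targets")
        specs = [MarginSpec(var, tgt) for var, tgt in margin_targets.items()]
        weights = rake_weights(survey, specs)
        pd.DataFrame(
            {
                "participant_id": weights.participant_ids,
                "weight": weights.weights,
            }
        ).to_csv(out / "weights.csv", index=False, float_format="%.10g")
        log.append(
            f"INFO: raking converged={weights.converged} "
            f"iterations={weights.iterations_used} "
            f"max_margin_error={weights.max_margin_error:.3g}"
        )

    # --- matrices ----------------------------------------------------------
    if stages["matrices"]:
        frames = []
        for stratum in ("urban", "rural", "all"):
            pop = pops[stratum]
            mats = setting_stratified_matrices(
                survey,
                weights,
                MATRIX_SCHEME,
                pop,
                stratum=stratum,
                attribution=config.attribution,
            )
            for label, mat in mats.items():
                frames.append(mat.to_dataframe())
                log.append(
                    f"INFO: matrix {stratum}/{label}: "
                    f"dropped {mat.n_dropped_missing_age} ageless contacts"
                )
        pd.concat(frames).to_csv(
            out / "matrices_long.csv", index=False, float_format="%.10g"
        )

    # --- descriptives ------------------------------------------------------
    if stages["describe"]:
        summ = participant_summaries(survey)
        summ.to_csv(out / "participant_summaries.csv", index=False, float_format="%.10g")
        med, q1, q3 = weighted_median_iqr(
            summ["degree_total"], weights.weights if weights else None
        )
        totals = contact_totals(survey)
        props = setting_proportions(survey, weights, groupby="age_band")
        props.table.to_csv(out / "setting_proportions.csv", float_format="%.10g")
        dist_tab, mob_tab = distance_mobility_tables(survey, weights)
        dist_tab.table.to_csv(out / "distance_distribution.csv", float_format="%.10g")
        if mob_tab is not None:
            mob_tab.table.to_csv(out / "mobility.csv", index=False, float_format="%.10g")
        rep = reporting_method_comparison(survey)
        desc = {
            "degree_total_median": med,
            "degree_total_iqr": [q1, q3],
            **totals,
        }
        if rep.applicable:
            desc["reporting_age_chi2"] = list(rep.age_chi2)
            desc["reporting_physical_chi2"] = list(rep.physical_chi2)
        with open(out / "descriptives.json", "w") as fh:
            json.dump(desc, fh, indent=1, default=float)
        log.append(f"INFO: weighted median degree {med:.1f} (IQR {q1:.0f}-{q3:.0f})")

    # --- regression --------------------------------------------------------
    if stages["regress"]:
        for response in ("degree_total", "contact_hours"):
            fit = fit_nb_model(survey, weights, response=response)
            rr = fit.relative_rates()
            if config.run_anova:
                an = fit.anova().set_index("term")["p"]
                rr["anova_p"] = rr["variable"].map(an)
            rr.to_csv(out / f"nb_{response}.csv", index=False, float_format="%.6g")
            log.append(
                f"INFO: NB fit {response}: dispersion={fit.dispersion:.3f}"
            )

    (out / "pipeline.log").write_text("\n".join(log) + "\n")

    files = sorted(
        p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "seed": config.seed,
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
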