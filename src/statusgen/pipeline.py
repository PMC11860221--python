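"""End-to-end orchestration: configuration, fixtures, stage running, report.

A run either simulates a pedigree from an embedded
:class:`~statusgen.simulate.SimulationConfig` or loads user-supplied
delimited-text person/panel/health tables, then executes the requested
analysis stages in dependency order and writes delimited-text tables plus a
machine-readable JSON summary. Re-running with an identical config
reproduces every numeric output bit for bit: the single seed fans out into
named per-stage streams, so toggling one stage never perturbs another's
draws. Warnings (unstable ratios, capped shares, non-convergence) are
surfaced in the JSON summary, never only in the log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import InvalidParameterError
from .simulate import (
    MediatorSpec,
    SimulationConfig,
    attach_mediators_health_panel,
    attach_observed_pgs,
    paper_scenario,
    read_persons,
    simulate_population,
    write_panel,
    write_persons,
)
from .scales import write_toy_crosswalk
from . import decomposition as dec
from . import mediation as med
from . import transmission as tra

logger = logging.getLogger("statusgen")

ALL_ANALYSES = ("decompose", "mediate", "transmit", "health", "trajectories")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``simulation`` or ``persons_path`` must be present. ``h2_snp``
    is only needed for the rescaling stage on user data; simulated data
    derive it from the latent score.
    """

    simulation: SimulationConfig | None = None
    mediators: MediatorSpec = field(default_factory=MediatorSpec)
    persons_path: str | None = None
    panel_path: str | None = None
    health_path: str | None = None
    crosswalk_path: str | None = None
    analyses: tuple = ALL_ANALYSES
    n_boot: int = 200
    seed: int = 0
    outdir: str = "statusgen_run"
    h2_snp: float | None = None

    def validate(self) -> None:
        if self.simulation is None and self.persons_path is None:
            raise InvalidParameterError(
                "either an embedded simulation config or persons_path is required"
            )
        unknown = set(self.analyses) - set(ALL_ANALYSES)
        if unknown:
            raise InvalidParameterError(f"unknown analyses: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if "simulation" in raw and raw["simulation"] is not None:
            raw["simulation"] = SimulationConfig(**raw["simulation"])
        if "mediators" in raw and raw["mediators"] is not None:
            raw["mediators"] = MediatorSpec(**raw["mediators"])
        if "analyses" in raw:
            raw["analyses"] = tuple(raw["analyses"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["analyses"] = list(self.analyses)
        return d

    def digest(self) -> str:
        """Hash of the analytic configuration (the output directory does not
        change what is computed)."""
        d = self.to_jsonable()
        d.pop("outdir", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    have = {type(h) for h in logger.handlers}
    if logging.StreamHandler not in have:
        logger.addHandler(logging.StreamHandler())
    fh = logging.FileHandler(outdir / "run.log", mode="a")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)


def _round_floats(obj, digits=10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, digits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), digits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages and write the report bundle.

    Returns the JSON-serializable summary that is also written to
    ``summary.json`` in the output directory.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    summary: dict = {
        "package_version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "warnings": [],
    }
    # independent per-stage streams: toggling one stage never perturbs the
    # draws of another
    stage_rng = {
        name: np.random.default_rng([config.seed % (2**31), 1000 + i])
        for i, name in enumerate(ALL_ANALYSES)
    }

    # ---- data stage -------------------------------------------------------
    panel = health = None
    if config.simulation is not None:
        ped = simulate_population(config.simulation)
        if ped.persons["observed_pgs"].isna().all():
            attach_observed_pgs(
                ped, config.simulation.pgs_target_r2 or 0.097
            )
        aug = attach_mediators_health_panel(ped, config.mediators)
        persons = aug.persons
        panel, health = aug.panel, aug.health
        full = ped.persons
        write_persons(persons, outdir / "persons.csv")
        write_panel(panel, outdir / "panel.csv")
        health.to_csv(outdir / "health.csv", index=False, na_rep="")
        moments = dict(ped.realized_moments)
        summary["warnings"].extend(moments.pop("warnings", []))
        summary["realized_moments"] = _round_floats(moments)
        summary["generator_truth"] = _round_floats(aug.truth)
        h2_latent = float(
            np.corrcoef(
                persons["additive_score"], persons["phenotype"]
            )[0, 1] ** 2
        )
    else:
        persons = read_persons(config.persons_path)
        full = persons
        if config.panel_path:
            panel = pd.read_csv(config.panel_path)
        if config.health_path:
            health = pd.read_csv(config.health_path)
        h2_latent = config.h2_snp

    # ---- decomposition ----------------------------------------------------
    if "decompose" in config.analyses:
        pop = dec.fit_population(persons)
        rows = [pop]
        ratios = []
        if persons["family_id"].duplicated().any():
            sib = dec.fit_within_sibship(persons)
            rows.append(sib)
            ratios.append(
                dec.attenuation_ratio(sib, pop, persons, config.n_boot, stage_rng["decompose"])
            )
        if persons.get("is_adoptee") is not None and persons["is_adoptee"].any():
            ado = dec.fit_adoption(persons)
            rows.append(ado)
            ratios.append(
                dec.attenuation_ratio(ado, pop, persons, config.n_boot, stage_rng["decompose"])
            )
        if "parental_status" in persons and persons["parental_status"].notna().any():
            pc = dec.fit_parental_control(persons)
            rows.append(pc)
            ratios.append(
                dec.attenuation_ratio(pc, pop, persons, config.n_boot, stage_rng["decompose"])
            )
        table = pd.DataFrame(
            {
                "design": [r.design for r in rows],
                "beta_pgs": [r.beta_pgs for r in rows],
                "se": [r.se for r in rows],
                "incremental_r2": [r.incremental_r2 for r in rows],
                "n": [r.n for r in rows],
            }
        )
        rt = pd.DataFrame(
            {
                "design": [a.design for a in ratios],
                "ratio": [a.ratio for a in ratios],
                "attenuation_pct": [a.attenuation_pct for a in ratios],
                "ci_low": [a.ci_low for a in ratios],
                "ci_high": [a.ci_high for a in ratios],
            }
        )
        table.to_csv(outdir / "decomposition_fits.csv", index=False)
        rt.to_csv(outdir / "decomposition_ratios.csv", index=False)
        indirect = [
            a.attenuation_pct for a in ratios
            if a.design in ("adoption", "parental_control")
        ]
        summary["decompose"] = _round_floats(
            {
                "fits": table.to_dict("records"),
                "ratios": rt.to_dict("records"),
                "direct_share_range": (
                    dec.decompose_population_effect(indirect).direct_range
                    if indirect and all(0 <= x <= 100 for x in indirect)
                    else None
                ),
            }
        )
        summary["warnings"].extend(
            w for r in rows for w in r.warnings
        )
        summary["warnings"].extend(a.warning for a in ratios if a.warning)

    # ---- mediation --------------------------------------------------------
    if "mediate" in config.analyses and panel is not None:
        mediators = [c for c in persons.columns if c.startswith("med_")]
        if mediators:
            results = med.life_course_mediation(
                persons, panel, mediators, n_boot=config.n_boot, rng=stage_rng["mediate"]
            )
            mt = med.results_table(results)
            mt.to_csv(outdir / "mediation.csv", index=False)
            summary["mediate"] = _round_floats(
                {
                    "waves": [
                        {
                            "wave": r.wave,
                            "n": r.n,
                            "total": r.total.estimate,
                            "proportion_mediated_total": r.proportion_mediated_total,
                            "proportion_mediated": r.proportion_mediated,
                        }
                        for r in results
                    ]
                }
            )

    # ---- transmission -----------------------------------------------------
    if "transmit" in config.analyses and "paternal_status" in persons:
        r_ig = tra.intergenerational_correlation(
            persons, n_boot=config.n_boot, rng=stage_rng["transmit"]
        )
        share = tra.genetic_confounding_share(
            persons, n_boot=config.n_boot, rng=stage_rng["transmit"]
        )
        block = {
            "r_intergen": r_ig.r,
            "r_ci": (r_ig.ci_low, r_ig.ci_high),
            "pgs_share_pct": share.share_pct,
            "share_ci": (share.ci_low, share.ci_high),
        }
        r2 = dec.fit_population(persons).incremental_r2
        if h2_latent is not None and 0 < r2 <= h2_latent <= 1:
            res = tra.rescale_to_snp_h2(share.share_pct, r2, h2_latent)
            block.update(
                rescaled_share_pct=res.rescaled_share_pct,
                other_share_pct=res.other_share_pct,
                k_rescale=res.k_rescale,
                capped=res.capped,
                h2_snp=res.h2_snp,
                r2_pgs=res.r2_pgs,
            )
            if res.capped:
                summary["warnings"].append("rescaled genetic share capped at 100%")
        if share.unstable:
            summary["warnings"].append(
                "intergenerational correlation unstable; mediated share flagged"
            )
        summary["transmit"] = _round_floats(block)

    # ---- health -----------------------------------------------------------
    if "health" in config.analyses and health is not None:
        table, averages = tra.health_confounding(persons, health)
        table.to_csv(outdir / "health_confounding.csv", index=False)
        summary["health"] = _round_floats({"average_attenuation_pct": averages})
        if table["unstable"].any():
            summary["warnings"].append(
                f"{int(table['unstable'].sum())} unstable health cells excluded"
            )

    # ---- trajectories -----------------------------------------------------
    if "trajectories" in config.analyses and panel is not None:
        profile = tra.career_trajectory_profile(panel, persons)
        profile.to_csv(outdir / "trajectories.csv", index=False)
        tra.plot_trajectories(profile, outdir / "trajectories.png")
        summary["trajectories"] = _round_floats(
            {
                "grand_mean_percentile_by_wave": profile.groupby("wave")
                .apply(
                    lambda g: float(np.average(g["mean_percentile"], weights=g["n"])),
                    include_groups=False,
                )
                .to_dict()
            }
        )

    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary


def generate_fixture(seed: int = 1, outdir: str = "fixture") -> dict:
    """Write the small packaged demo dataset: a ~2,000-family calibrated
    pedigree (persons, career panel, health) plus the synthetic toy
    crosswalk. Returns file paths, sha256 checksums and realized moments."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = paper_scenario(n_families=2000, seed=seed)
    ped = simulate_population(cfg)
    aug = attach_mediators_health_panel(ped)
    paths = {
        "persons": out / "persons.csv",
        "panel": out / "panel.csv",
        "health": out / "health.csv",
        "crosswalk": out / "toy_crosswalk.csv",
    }
    write_persons(aug.persons, paths["persons"])
    write_panel(aug.panel, paths["panel"])
    aug.health.to_csv(paths["health"], index=False, na_rep="")
    write_toy_crosswalk(paths["crosswalk"])
    checksums = {
        k: hashlib.sha256(p.read_bytes()).hexdigest() for k, p in paths.items()
    }
    return {
        "paths": {k: str(p) for k, p in paths.items()},
        "checksums": checksums,
        "realized_moments": ped.realized_moments,
        "truth": aug.truth,
    }
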