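"""End-to-end study orchestration from a single declarative config.

A run executes: exclusion -> scoring and prevalence -> per-group network
estimation -> centrality -> bootstrap stability -> permutation network
comparison -> covariate-adjusted and delta networks -> figures, writing every
stage's outputs plus a manifest (package version, seeds, input digests, row
accounting) into a fresh run directory. One master seed deterministically
derives the per-stage seeds, so a single integer reproduces the whole run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .centrality import centrality_profile
from .ggm import GgmConfig, covariate_network, delta_network, estimate_network
from .nct import NctConfig, compare_networks
from .plotting import layout_fruchterman_reingold, plot_centrality_bars, render_network
from .simulate import SyntheticScenario, simulate_study
from .stability import (BootConfig, bootstrap_difference_tests, bootstrap_networks,
                        case_dropping_stability, edge_accuracy)
from .survey import DEMOGRAPHICS, GROUPS, apply_exclusion, cronbach_alpha, \
    GAD_ITEMS, PHQ_ITEMS, prevalence_summary, read_table, score_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one study run needs; round-trips losslessly through YAML."""

    input_csv: str | None = None            # pre-made table; else simulate
    scenario: SyntheticScenario | None = None
    ggm: GgmConfig = field(default_factory=GgmConfig)
    boot: BootConfig = field(default_factory=BootConfig)
    nct: NctConfig = field(default_factory=NctConfig)
    covariates: tuple[str, ...] = DEMOGRAPHICS
    stability_indices: tuple[str, ...] = ("nodal_strength", "bridge_strength")
    run_stability: bool = True
    run_nct: bool = True
    run_covariate_control: bool = True
    make_figures: bool = True
    seed: int = 0
    outdir: str = "runs"

    def __post_init__(self) -> None:
        if self.input_csv is None and self.scenario is None:
            self.scenario = SyntheticScenario(seed=self.seed)
        if self.input_csv is not None and not Path(self.input_csv).exists():
            raise FileNotFoundError(f"input table not found: {self.input_csv}")
        # one master seed -> fixed per-stage seeds (all < 2**31)
        ss = np.random.SeedSequence(self.seed)
        stage = [int(s) % (2 ** 31) for s in ss.generate_state(3)]
        self.boot = dataclasses.replace(self.boot, seed=stage[0])
        self.nct = dataclasses.replace(self.nct, seed=stage[1])

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        for key, typ in (("scenario", SyntheticScenario), ("ggm", GgmConfig),
                         ("boot", BootConfig), ("nct", NctConfig)):
            if doc.get(key) is not None:
                sub = doc[key]
                for k, v in sub.items():
                    if isinstance(v, list):
                        sub[k] = tuple(v)
                doc[key] = typ(**sub)
        for k in ("covariates", "stability_indices"):
            if doc.get(k) is not None:
                doc[k] = tuple(doc[k])
        return cls(**doc)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _new_run_dir(outdir: str | Path, seed: int) -> Path:
    base = Path(outdir)
    base.mkdir(parents=True, exist_ok=True)
    k = 0
    while True:
        cand = base / f"run-seed{seed}-{k:03d}"
        if not cand.exists():
            cand.mkdir()
            return cand
        k += 1


def run_study(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    run_dir = _new_run_dir(config.outdir, config.seed)
    manifest: dict = {"package_version": __version__, "seed": config.seed,
                      "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
                      "stages": {}}
    stage = "input"
    try:
        if config.input_csv is not None:
            table = read_table(config.input_csv)
            manifest["input"] = {"path": config.input_csv,
                                 "sha256": _digest(Path(config.input_csv))}
        else:
            table, model = simulate_study(config.scenario)
            model.to_json(run_dir / "ground_truth.json")
            table.to_csv(run_dir / "simulated_table.csv", index=False)
            manifest["input"] = {"scenario": dataclasses.asdict(config.scenario)}
        manifest["stages"]["input"] = {"n_rows": len(table)}

        stage = "exclusion"
        retained, n_excluded = apply_exclusion(table)
        manifest["stages"]["exclusion"] = {
            "n_in": len(table), "n_excluded": n_excluded, "n_retained": len(retained)}
        logger.info("exclusion: %d -> %d rows (%d excluded)",
                    len(table), len(retained), n_excluded)

        stage = "scoring"
        scored = score_table(retained)
        scored.to_csv(run_dir / "scored.csv", index=False)
        prevalence = {g: prevalence_summary(scored, g)
                      for g in GROUPS if (scored["group"] == g).any()}
        alphas = {
            "phq9": cronbach_alpha(retained[list(PHQ_ITEMS)]),
            "gad7": cronbach_alpha(retained[list(GAD_ITEMS)]),
        }
        (run_dir / "prevalence.json").write_text(
            json.dumps({"prevalence": prevalence, "cronbach_alpha": alphas}, indent=1))
        manifest["stages"]["scoring"] = {"cronbach_alpha": alphas}

        stage = "network_estimation"
        groups = {g: retained[retained["group"] == g] for g in GROUPS
                  if (retained["group"] == g).any()}
        nets = {g: estimate_network(t, config.ggm) for g, t in groups.items()}
        for g, net in nets.items():
            net.save(run_dir / f"network_{g}")
        manifest["stages"]["network_estimation"] = {
            g: {"n": net.n, "edges": net.edge_count,
                "possible_edges": net.n_possible_edges,
                "density_percent": net.density_percent,
                "lambda_selected": net.lambda_selected}
            for g, net in nets.items()}

        stage = "centrality"
        profiles = {g: centrality_profile(net) for g, net in nets.items()}
        for g, prof in profiles.items():
            prof.save(run_dir / f"centrality_{g}.csv")
        manifest["stages"]["centrality"] = {
            g: {"global_strength": prof.global_strength} for g, prof in profiles.items()}

        if config.run_stability:
            stage = "stability"
            stab_meta = {}
            for g, t in groups.items():
                draws = bootstrap_networks(t, config.ggm, config.boot)
                edge_accuracy(t, config.ggm, config.boot, draws=draws).to_csv(
                    run_dir / f"edge_ci_{g}.csv", index=False)
                ed, sd = bootstrap_difference_tests(t, config.ggm, config.boot,
                                                    draws=draws)
                ed.to_csv(run_dir / f"edge_diff_{g}.csv")
                sd.to_csv(run_dir / f"strength_diff_{g}.csv")
                cs = {}
                for index in config.stability_indices:
                    res = case_dropping_stability(t, index, config.ggm, config.boot)
                    cs[index] = res.cs_coefficient
                    pd.DataFrame({
                        "drop": list(res.drop_grid),
                        "proportion_ok": [res.proportion_ok[d] for d in res.drop_grid],
                        "n_skipped": [res.n_skipped[d] for d in res.drop_grid],
                    }).to_csv(run_dir / f"case_dropping_{index}_{g}.csv", index=False)
                stab_meta[g] = {"cs_coefficient": cs, "n_boot": config.boot.n_boot}
            manifest["stages"]["stability"] = stab_meta

        if config.run_nct and len(groups) == 2:
            stage = "network_comparison"
            nct_res = compare_networks(groups["school"], groups["vacation"],
                                       config.ggm, config.nct)
            nct_res.save(run_dir / "nct")
            manifest["stages"]["network_comparison"] = {
                "p_global": nct_res.p_global, "p_structure": nct_res.p_structure,
                "global_strengths": list(nct_res.global_strengths),
                "n_perm": nct_res.n_perm}

        if config.run_covariate_control:
            stage = "covariate_control"
            cov_meta = {}
            for g, t in groups.items():
                cov_net = covariate_network(t, config.covariates, config.ggm)
                cov_net.save(run_dir / f"network_covadj_{g}")
                delta = delta_network(nets[g], cov_net)
                pd.DataFrame(delta.delta, index=list(delta.labels),
                             columns=list(delta.labels)).to_csv(
                    run_dir / f"delta_network_{g}.csv")
                cov_meta[g] = {"max_delta": delta.max_delta}
            manifest["stages"]["covariate_control"] = cov_meta

        if config.make_figures:
            stage = "figures"
            ref = "school" if "school" in nets else next(iter(nets))
            layout = layout_fruchterman_reingold(nets[ref], seed=config.seed)
            for g, net in nets.items():
                render_network(net, layout, title=f"{g} network").save(
                    run_dir / f"network_{g}.png")
            fig = plot_centrality_bars(profiles)
            fig.savefig(run_dir / "centrality_strength.png", dpi=150,
                        bbox_inches="tight")
            import matplotlib.pyplot as plt
            plt.close(fig)

        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    config.to_yaml(run_dir / "config.yaml")
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return run_dir
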