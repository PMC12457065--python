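"""End-to-end orchestration: simulate (or load) -> trajectory classes ->
per-group cross-lagged networks -> centrality -> robustness -> report.

Every source of randomness is derived from one master seed through
:func:`stage_seeds` (numpy ``SeedSequence`` spawning, folded below 2^31),
so a run is a pure function of its configuration.  Each stage writes its
artifacts under the output directory and a manifest records a SHA-256 hash
of every file the report cites; on stage failure the manifest is still
written with the failing stage named.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clpn as clpn_mod
from . import gmm as gmm_mod
from . import io as io_mod
from . import metrics as metrics_mod
from . import stability as stability_mod
from .simulate import default_growth_spec, generate_cptsd_panel

STAGES = ("simulate", "gmm", "clpn", "stability", "report")


def stage_seeds(master_seed: int, n: int = 8) -> list[int]:
    """Deterministic per-stage seeds below 2^31 derived from the master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


@dataclass
class RunConfig:
    """Reproducible configuration for one full pipeline run."""

    out_dir: str = "results/run"
    input_path: str | None = None  # when None, simulate the default panel
    n_subjects: int = 1277
    k_min: int = 1
    k_max: int = 3
    n_starts: int = 20
    blrt_reps: int = 19
    blrt_starts: int = 5
    min_class_prop: float = 0.05
    wave_pairs: tuple[tuple[int, int], ...] = ((1, 2), (2, 3))
    n_folds: int = 10
    lambda_rule: str = "min"
    display_threshold: float = 0.05
    bootstrap_B: int = 1000
    casedrop_B: int = 250
    fixed_lambda_bootstrap: bool = True
    run_stability: bool = True
    master_seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["wave_pairs"] = tuple(tuple(p) for p in d["wave_pairs"])
        return cls(**d)


@dataclass
class RunReport:
    config: RunConfig
    selected_K: int
    class_sizes: dict[str, int]
    class_props: dict[str, float]
    fit_table: pd.DataFrame
    networks: dict[str, dict]
    failed_stage: str | None = None

    def to_dict(self) -> dict:
        return {
            "selected_K": self.selected_K,
            "class_sizes": self.class_sizes,
            "class_props": self.class_props,
            "fit_table": json.loads(self.fit_table.to_json(orient="records")),
            "networks": self.networks,
            "failed_stage": self.failed_stage,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _group_labels(k: int) -> list[str]:
    # class 1 is canonically the high-intercept class
    if k == 2:
        return ["high_risk", "resistance"]
    return [f"class_{i + 1}" for i in range(k)]


def run_pipeline(config: RunConfig) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    seeds = stage_seeds(config.master_seed)
    written: list[Path] = []
    stage = "simulate"
    try:
        # ---- stage 1: data -------------------------------------------------
        if config.input_path is not None:
            panel = io_mod.read_panel(config.input_path)
        else:
            spec = default_growth_spec(n_subjects=config.n_subjects, seed=seeds[0])
            panel = generate_cptsd_panel(spec)
            io_mod.write_panel(panel, out / "panel.csv", meta={"spec": dataclasses.asdict(spec)})
            written += [out / "panel.csv", out / "panel.meta.json"]

        # ---- stage 2: trajectory classes ----------------------------------
        stage = "gmm"
        fits = []
        for k in range(config.k_min, config.k_max + 1):
            model = gmm_mod.fit_gmm(panel, k, n_starts=config.n_starts, seed=seeds[1] + k)
            idx = gmm_mod.fit_indices(model)
            if k >= 2:
                idx.blrt_p = gmm_mod.blrt(
                    panel,
                    k,
                    n_boot=config.blrt_reps,
                    n_starts=config.blrt_starts,
                    seed=seeds[2] + k,
                )
                idx.lmr_p = gmm_mod.lmr_pvalue(
                    fits[-1][0].loglik, model.loglik, model.n_subjects
                )
            fits.append((model, idx))
        selection = gmm_mod.select_model(fits, min_class_prop=config.min_class_prop)
        best_model = fits[selection.recommended_K - config.k_min][0]
        assignment = gmm_mod.classify(best_model)
        selection.table.to_csv(out / "fit_indices.csv", index=False)
        (out / "model.json").write_text(
            json.dumps(best_model.to_dict(), indent=2, sort_keys=True)
        )
        assign_df = pd.DataFrame(
            {
                "id": panel["id"],
                "modal_class": assignment.modal_class,
                "max_posterior": assignment.max_posterior,
            }
        )
        assign_df.to_csv(out / "assignments.csv", index=False)
        written += [out / "fit_indices.csv", out / "model.json", out / "assignments.csv"]

        labels = _group_labels(selection.recommended_K)
        class_sizes = {
            labels[k]: int((assignment.modal_class == k + 1).sum())
            for k in range(selection.recommended_K)
        }
        class_props = {g: c / len(panel) for g, c in class_sizes.items()}

        # ---- stage 3: networks + centrality -------------------------------
        stage = "clpn"
        networks: dict[str, dict] = {}
        nets: dict[str, clpn_mod.CLPNetwork] = {}
        for k, label in enumerate(labels):
            ids = panel["id"][assignment.modal_class == k + 1].to_numpy()
            for pair in config.wave_pairs:
                cfg = clpn_mod.LassoConfig(
                    n_folds=config.n_folds,
                    lambda_rule=config.lambda_rule,
                    fold_seed=seeds[3] + 10 * k + pair[0],
                )
                net = clpn_mod.fit_clpn(panel, ids, pair, cfg, group=label)
                key = f"{label}_T{pair[0]}T{pair[1]}"
                nets[key] = net
                net.edge_list().to_csv(out / f"edges_{key}.csv", index=False)
                net.matrix_frame().to_csv(out / f"matrix_{key}.csv")
                display = clpn_mod.apply_display_threshold(net, config.display_threshold)
                try:
                    import networkx as nx

                    nx.write_graphml(display.to_graph(), out / f"network_{key}.graphml")
                    written.append(out / f"network_{key}.graphml")
                except ImportError:
                    pass
                table = metrics_mod.centrality_table(net)
                table.frame().to_csv(out / f"centrality_{key}.csv", index=False)
                written += [
                    out / f"edges_{key}.csv",
                    out / f"matrix_{key}.csv",
                    out / f"centrality_{key}.csv",
                ]
                offdiag = net.W[~np.eye(len(net.nodes), dtype=bool)]
                edges = net.edge_list()
                cross = edges[edges["source"] != edges["target"]]
                top3 = cross.reindex(
                    cross["weight"].abs().sort_values(ascending=False).index
                ).head(3)
                networks[key] = {
                    "group": label,
                    "wave_pair": list(pair),
                    "n": net.n,
                    "n_nonzero_cross_lagged": int(np.sum(offdiag != 0.0)),
                    "top_edges": [
                        {"source": r.source, "target": r.target, "weight": round(r.weight, 6)}
                        for r in top3.itertuples()
                    ],
                    "top_out_EI": metrics_mod.rank_centrality(table, "out_EI")[0],
                    "top_in_EI": metrics_mod.rank_centrality(table, "in_EI")[0],
                }

        # ---- stage 4: robustness ------------------------------------------
        if config.run_stability:
            stage = "stability"
            cs_rows = []
            for k, label in enumerate(labels):
                ids = panel["id"][assignment.modal_class == k + 1].to_numpy()
                for pair in config.wave_pairs:
                    key = f"{label}_T{pair[0]}T{pair[1]}"
                    cfg = nets[key].config
                    boot = stability_mod.bootstrap_edges(
                        panel,
                        ids,
                        pair,
                        cfg,
                        B=config.bootstrap_B,
                        seed=seeds[4] + 10 * k + pair[0],
                        fixed_lambda=config.fixed_lambda_bootstrap,
                        group=label,
                    )
                    boot.summary_frame().to_csv(out / f"bootstrap_{key}.csv", index=False)
                    written.append(out / f"bootstrap_{key}.csv")
                    for metric in ("in_EI", "out_EI"):
                        cs = stability_mod.casedrop_cs(
                            panel,
                            ids,
                            pair,
                            cfg,
                            metric=metric,
                            B_per_level=config.casedrop_B,
                            seed=seeds[5] + 10 * k + pair[0],
                            fixed_lambda=config.fixed_lambda_bootstrap,
                            group=label,
                        )
                        cs_rows.append(
                            {
                                "group": label,
                                "wave_pair": f"{pair[0]}->{pair[1]}",
                                "metric": metric,
                                "cs": cs.cs_coefficient,
                            }
                        )
                        networks[key][f"cs_{metric}"] = cs.cs_coefficient
            pd.DataFrame(cs_rows).to_csv(out / "cs_coefficients.csv", index=False)
            written.append(out / "cs_coefficients.csv")

        # ---- stage 5: report ----------------------------------------------
        stage = "report"
        report = RunReport(
            config=config,
            selected_K=selection.recommended_K,
            class_sizes=class_sizes,
            class_props=class_props,
            fit_table=selection.table,
            networks=networks,
        )
        (out / "report.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True)
        )
        written.append(out / "report.json")
        _write_manifest(out, written, failed_stage=None)
        return report
    except Exception:
        _write_manifest(out, written, failed_stage=stage)
        raise


def _write_manifest(out: Path, files: list[Path], failed_stage: str | None) -> None:
    manifest = {
        "failed_stage": failed_stage,
        "files": {p.name: _sha256(p) for p in files if p.exists()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
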