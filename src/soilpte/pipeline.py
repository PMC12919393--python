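"""End-to-end orchestration: screen -> indices -> PMF -> kriging -> RF -> risk.

Each stage consumes and produces plain-text artifacts inside the output
directory, so any stage can be re-run standalone.  One global seed fans out
deterministically to per-stage seeds; every run writes ``run_info.txt``
with the configuration hash, the seed and per-stage timings.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core, indices, kriging, pmf, rf, risk, screening, synthetic
from .core import ELEMENTS, LAND_USES


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 42
    out_dir: str = "soilpte_out"
    input_path: str | None = None          # None -> simulate
    stages: dict = field(default_factory=lambda: {
        "simulate": True, "screen": True, "indices": True, "pmf": True,
        "krige": True, "rf": True, "risk": True,
    })
    simulate: dict = field(default_factory=lambda: {
        "k": 4, "n_per_landuse": 24, "noise_cv": 0.2, "censor_policy": "flag",
    })
    pmf_opts: dict = field(default_factory=lambda: {
        "k": 4, "n_starts": 10, "robust": True, "error_fraction": 0.1,
        "bootstrap_runs": 20, "outlier_screen": True,
    })
    krige_opts: dict = field(default_factory=lambda: {
        "n_lags": 12, "grid_size": 25, "variables": None,  # None -> all
    })
    rf_opts: dict = field(default_factory=lambda: {
        "n_trees": 300, "train_frac": 0.7, "targets": None,  # None -> all
        "use_pmf_features": True, "winsorize_full_vector": True,
    })
    risk_opts: dict = field(default_factory=lambda: {
        "n_iter": 10_000, "exposure_point": "point", "toxicity_point": "point",
        "exposure_mc": "mc", "toxicity_mc": "mc",
    })

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise PipelineConfigError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, dict) and isinstance(value, dict):
                current.update(value)
            else:
                setattr(cfg, key, value)
        return cfg

    def validate(self) -> None:
        if self.rf_opts.get("use_pmf_features") and self.stages.get("rf") \
                and not self.stages.get("pmf"):
            raise PipelineConfigError(
                "rf stage requests PMF contribution features but the pmf "
                "stage is disabled"
            )
        if self.input_path is None and not self.stages.get("simulate"):
            raise PipelineConfigError("no input file and simulate disabled")

    def digest(self) -> str:
        blob = yaml.safe_dump({
            "seed": self.seed, "input": self.input_path, "stages": self.stages,
            "simulate": self.simulate, "pmf": self.pmf_opts,
            "krige": self.krige_opts, "rf": self.rf_opts, "risk": self.risk_opts,
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Deterministic fan-out of one global seed into per-stage seeds."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns a manifest of the
    artifacts written."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest: dict = {"out_dir": str(out), "config_hash": config.digest(),
                      "seed": config.seed, "artifacts": [], "timings": {}}
    log_lines = [f"config_hash {config.digest()}", f"seed {config.seed}"]

    def save(df: pd.DataFrame, name: str, **kw):
        path = out / name
        df.to_csv(path, float_format="%.10g", **kw)
        manifest["artifacts"].append(str(path))

    def timed(name):
        class _T:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, *exc):
                dt = time.perf_counter() - self_inner.t0
                manifest["timings"][name] = dt
                log_lines.append(f"stage {name} {dt:.2f}s")
                return False
        return _T()

    # ------------------------------------------------------------------ data
    refs = core.load_reference_tables()
    truth = None
    if config.input_path is not None:
        ds = core.read_samples(config.input_path, mdl=refs.mdl)
    else:
        with timed("simulate"):
            spec = synthetic.make_default_sourcespec(
                k=config.simulate["k"], seed=seeds[0],
                noise_cv=config.simulate["noise_cv"])
            ds, truth = synthetic.synthesize_dataset(
                spec, config.simulate["n_per_landuse"], mdl=refs.mdl,
                seed=seeds[0], censor_policy=config.simulate["censor_policy"])
        core.write_samples(ds, out / "samples.csv")
        synthetic.write_truth(truth, out / "truth_G.csv", out / "truth_F.csv")
        manifest["artifacts"] += [str(out / "samples.csv"),
                                  str(out / "truth_G.csv"), str(out / "truth_F.csv")]

    # ---------------------------------------------------------------- screen
    if config.stages.get("screen"):
        with timed("screen"):
            screen = screening.normality_screen(ds)
            rho, pvals, flags = screening.spearman_matrix(ds)
        save(screen, "normality.csv")
        save(rho, "spearman_rho.csv")
        save(pvals, "spearman_p.csv")
        save(flags, "spearman_flags.csv")
        adj = screening.holm_adjust(
            pvals.to_numpy()[np.triu_indices(len(ELEMENTS), 1)])
        holm = pd.DataFrame({"pair": [
            f"{ELEMENTS[i]}-{ELEMENTS[j]}"
            for i, j in zip(*np.triu_indices(len(ELEMENTS), 1))],
            "p_holm": adj}).set_index("pair")
        save(holm, "spearman_p_holm.csv")

    # --------------------------------------------------------------- indices
    if config.stages.get("indices"):
        with timed("indices"):
            table = indices.index_table(ds, refs)
        save(table.per_element, "indices_per_element.csv", index=False)
        save(table.per_sample, "indices_per_sample.csv", index=False)
        save(table.cf_severe_rate, "cf_severe_rate.csv")

    # ------------------------------------------------------------------- pmf
    solution = None
    if config.stages.get("pmf"):
        with timed("pmf"):
            if config.pmf_opts.get("outlier_screen"):
                flags_out = pmf.flag_outlier_samples(ds)
            else:
                flags_out = np.zeros(ds.n, bool)
            U = pmf.build_uncertainty_matrix(
                ds, config.pmf_opts["error_fraction"], refs.mdl)
            X = ds.concentrations()
            solution = pmf.fit_pmf(
                X, U, config.pmf_opts["k"],
                n_starts=config.pmf_opts["n_starts"], seed=seeds[1],
                robust=config.pmf_opts["robust"]).normalized()
            bs = pmf.bootstrap_diagnostic(
                X, U, solution, n_runs=config.pmf_opts["bootstrap_runs"],
                seed=seeds[2])
            disp = pmf.disp_diagnostic(X, U, solution, seed=seeds[2])
        k = solution.F.shape[0]
        save(pd.DataFrame(solution.G, columns=[f"F{f+1}" for f in range(k)]),
             "pmf_G.csv", index=False)
        save(pd.DataFrame(solution.F, columns=list(ELEMENTS),
                          index=[f"F{f+1}" for f in range(k)]), "pmf_F.csv")
        save(pd.DataFrame(pmf.element_contribution_percent(solution.F),
                          columns=list(ELEMENTS),
                          index=[f"F{f+1}" for f in range(k)]),
             "pmf_element_contribution_pct.csv")
        share = pmf.factor_total_share(solution.G, solution.F)
        save(pd.DataFrame({"factor": [f"F{f+1}" for f in range(k)],
                           "share_pct": share}).set_index("factor"),
             "pmf_factor_share.csv")
        with open(out / "pmf_report.txt", "w") as fh:
            fh.write(f"Q {solution.Q:.6g}\nQ_expected {solution.Q_expected:.6g}\n"
                     f"Q/Q_expected {solution.Q / solution.Q_expected:.6g}\n"
                     f"converged {solution.converged}\n"
                     f"outlier-flagged samples {int(flags_out.sum())}\n"
                     f"bootstrap runs {bs.bs_runs} (skipped {bs.bs_skipped})\n")
            for f, pct in bs.bs_mapped_pct.items():
                fh.write(f"bootstrap factor F{f+1} mapped {pct:.1f}%\n")
            fh.write(f"disp probes {disp.disp_probes} max_dQ% "
                     f"{disp.disp_max_dq_pct:.4f} swaps {disp.disp_swaps} "
                     f"stable {disp.disp_stable}\n")
        manifest["artifacts"].append(str(out / "pmf_report.txt"))

    # ----------------------------------------------------------------- krige
    if config.stages.get("krige"):
        with timed("krige"):
            gsize = config.krige_opts["grid_size"]
            gx = np.linspace(0, synthetic.DOMAIN_SIZE, gsize)
            gy = np.linspace(0, synthetic.DOMAIN_SIZE, gsize)
            variables = config.krige_opts.get("variables") or list(ELEMENTS)
            columns: dict[str, np.ndarray] = {
                v: ds.df[v].to_numpy(float) for v in variables}
            if solution is not None:
                Gn = pmf.normalize_contributions(solution.G)
                for f in range(Gn.shape[1]):
                    columns[f"F{f+1}"] = Gn[:, f]
            coords = ds.coords
            rows = []
            for name, z in columns.items():
                pts = np.column_stack([coords, z])
                lag, gam, cnt = kriging.empirical_semivariogram(
                    pts, n_lags=config.krige_opts["n_lags"])
                model = kriging.fit_spherical_model(lag, gam, cnt)
                surf = kriging.krige_grid(pts, model, gx, gy)
                kriging.write_esri_ascii(surf, out / f"krige_{name}.asc")
                manifest["artifacts"].append(str(out / f"krige_{name}.asc"))
                rows.append({"variable": name, "nugget": model.nugget,
                             "sill": model.sill, "range_m": model.range_a})
        save(pd.DataFrame(rows).set_index("variable"), "variograms.csv")

    # -------------------------------------------------------------------- rf
    if config.stages.get("rf"):
        with timed("rf"):
            targets = config.rf_opts.get("targets") or list(ELEMENTS)
            Gfeat = solution.G if (solution is not None and
                                   config.rf_opts.get("use_pmf_features")) else None
            X_all, _ = rf.build_feature_matrix(ds, Gfeat)
            metrics_rows = []
            imp_rows = {}
            for ti, el in enumerate(targets):
                y = ds.df[el].to_numpy(float)
                if config.rf_opts.get("winsorize_full_vector", True):
                    y = rf.winsorize(y)
                tr, te = rf.split_data(ds.n, config.rf_opts["train_frac"],
                                       seed=seeds[3] + ti)
                if not config.rf_opts.get("winsorize_full_vector", True):
                    lo, hi = np.percentile(y[tr], [5, 95])
                    y = np.clip(y, lo, hi)
                model = rf.train_rf(X_all.iloc[tr], y[tr],
                                    n_trees=config.rf_opts["n_trees"],
                                    seed=seeds[4] + ti)
                m = rf.evaluate(model, X_all.iloc[te], y[te], y[tr].mean())
                m["element"] = el
                metrics_rows.append(m)
                imp_rows[el] = rf.permutation_importance(
                    model, n_repeats=3, seed=seeds[5] + ti)
        save(pd.DataFrame(metrics_rows).set_index("element"), "rf_metrics.csv")
        save(pd.DataFrame(imp_rows), "rf_importance.csv")

    # ------------------------------------------------------------------ risk
    if config.stages.get("risk"):
        with timed("risk"):
            means, grand = core.landuse_means(ds)
            exp_p = risk.load_exposure(config.risk_opts["exposure_point"])
            tox_p = risk.load_toxicity(config.risk_opts["toxicity_point"])
            exp_m = risk.load_exposure(config.risk_opts["exposure_mc"])
            tox_m = risk.load_toxicity(config.risk_opts["toxicity_mc"])
            det_rows, mc_rows = [], []
            for receptor in risk.RECEPTORS:
                for lu in [l for l in LAND_USES if l in means.index]:
                    conc = means.loc[lu].to_dict()
                    r = risk.deterministic_risk(conc, exp_p, tox_p, receptor)
                    det_rows.append({"receptor": receptor, "land_use": lu,
                                     "HI": r.hi, "TCR": r.tcr})
                r = risk.deterministic_risk(grand.to_dict(), exp_p, tox_p, receptor)
                det_rows.append({"receptor": receptor, "land_use": "ALL",
                                 "HI": r.hi, "TCR": r.tcr})
                mc = risk.monte_carlo_risk(grand.to_dict(), exp_m, tox_m,
                                           receptor,
                                           n_iter=config.risk_opts["n_iter"],
                                           seed=seeds[6])
                hi_sh, tcr_sh = risk.risk_shares(mc)
                row = {"receptor": receptor, "HI_mean": mc.hi,
                       "TCR_mean": mc.tcr}
                row.update({f"HI_{k2}": v for k2, v in mc.summary["HI"].items()})
                row.update({f"TCR_{k2}": v for k2, v in mc.summary["TCR"].items()})
                row.update({f"HIshare_{el}": hi_sh.get(el, 0.0) for el in ELEMENTS})
                row.update({f"TCRshare_{el}": tcr_sh.get(el, 0.0) for el in ELEMENTS})
                mc_rows.append(row)
        save(pd.DataFrame(det_rows), "risk_deterministic.csv", index=False)
        save(pd.DataFrame(mc_rows), "risk_montecarlo.csv", index=False)

    with open(out / "run_info.txt", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    manifest["artifacts"].append(str(out / "run_info.txt"))
    return manifest
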