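"""End-to-end demonstration workflow: simulate -> analyze -> report.

:func:`run_demo` exercises every analysis in the package on synthetic data
from :mod:`assaykit.simulate` and writes per-assay CSV/JSON results plus a
summary report and a :class:`RunManifest` into a working directory.  Reruns
with the same seed reproduce byte-identical result CSVs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from . import __version__
from .cellassays import resection_ssdna, tmej_activity
from .doseresponse import fit_4pl
from .enzymology import classify_modality, delta_tm, initial_rates
from .plates import plate_median_normalize, write_measurements
from .screen import score_screen, screen_qc
from .simulate import (
    GeneratorConfig,
    gen_dose_response,
    gen_melt,
    gen_progress_grid,
    gen_reporter,
    gen_resection,
    gen_screen,
)

__all__ = ["RunManifest", "run_demo"]


@dataclass
class RunManifest:
    """Provenance record written next to every demo run's outputs."""

    command: str
    seed: int
    package_version: str
    parameters: dict
    config_hash: str = ""
    created: str = ""
    outputs: list[str] = field(default_factory=list)
    status: str = "ok"

    def __post_init__(self):
        if not self.config_hash:
            blob = json.dumps(self.parameters, sort_keys=True, default=str).encode()
            self.config_hash = hashlib.sha256(blob).hexdigest()[:16]
        if not self.created:
            self.created = datetime.now(timezone.utc).isoformat()

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")


def run_demo(
    workdir,
    seed: int = 0,
    *,
    n_sirnas: int = 1418,
    n_spiked: int = 20,
    spike_effect: float = -2.0,
) -> dict:
    """Generate, analyze and report every assay family on synthetic data.

    Stages: chemosensitization screen (with ``n_spiked`` spiked sensitizers of
    drug-specific log2 effect ``spike_effect``), biochemical IC50, reporter
    EC50, mechanism-of-action classification on both substrate grids, DSF
    thermal shifts, and resection ssDNA%.  Each stage writes its simulated
    measurements and results under ``workdir``; a ``report.json`` /
    ``report.md`` pair and a ``manifest.json`` summarize the run.

    Returns the report dictionary (recovered quantities vs generating truth).
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    params = dict(n_sirnas=n_sirnas, n_spiked=n_spiked, spike_effect=spike_effect)
    manifest = RunManifest(command="run_demo", seed=seed, package_version=__version__, parameters=params)
    cfg = GeneratorConfig(seed=seed)
    report: dict = {"seed": seed}
    outputs: list[str] = []

    def save_csv(df, rel, schema=None):
        path = workdir / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        if schema:
            write_measurements(df, path, schema)
        else:
            df.to_csv(path, index=False)
        outputs.append(rel)

    try:
        # -- screen ---------------------------------------------------------
        rng = np.random.default_rng(np.random.SeedSequence([seed % 2**31, 7]))
        spiked = [f"siRNA_{i + 1:04d}" for i in rng.choice(n_sirnas, size=n_spiked, replace=False)]
        effects = {s: (0.0, spike_effect) for s in spiked}
        wells, truth = gen_screen(n_sirnas, cfg, effects=effects)
        save_csv(wells, "screen/measurements.csv", schema="screen")
        save_csv(truth, "screen/truth.csv")
        results = score_screen(wells)
        save_csv(results, "screen/results.csv")
        qc = screen_qc(plate_median_normalize(wells))
        save_csv(qc, "screen/qc.csv")
        hits = set(results.loc[results["hit"], "perturbation_id"])
        report["screen"] = {
            "n_scored": int(len(results)),
            "n_hits": int(results["hit"].sum()),
            "n_spiked": n_spiked,
            "spiked_recovered": int(len(hits & set(spiked))),
            "qc_all_plates_pass": bool(~qc["flagged"].any()),
        }

        # -- biochemical IC50 ----------------------------------------------
        dr, dr_truth = gen_dose_response({"xc50": 7.9e-9}, "halflog_12uM", config=cfg)
        save_csv(dr, "ic50/dose_response.csv", schema="dose_response")
        samples = dr[dr["role"] == "sample"]
        fit = fit_4pl(samples["concentration_molar"], samples["signal"])
        report["ic50"] = {
            "true_nM": dr_truth["xc50"] * 1e9,
            "fitted_nM": fit.xc50 * 1e9,
            "hill": fit.hill,
            "converged": fit.converged,
        }
        (workdir / "ic50/fit.json").write_text(json.dumps(report["ic50"], indent=2))
        outputs.append("ic50/fit.json")

        # -- reporter EC50 ---------------------------------------------------
        rep_df, rep_truth = gen_reporter(150e-9, config=cfg)
        save_csv(rep_df, "reporter/reporter.csv", schema="reporter")
        act = tmej_activity(rep_df)
        doses = act[~act["is_dmso"]]
        rfit = fit_4pl(doses["conc_molar"], doses["activity"])
        report["reporter"] = {
            "true_nM": rep_truth["xc50"] * 1e9,
            "fitted_nM": rfit.xc50 * 1e9,
            "dmso_median_activity": float(np.median(act.loc[act["is_dmso"], "activity"])),
        }
        (workdir / "reporter/fit.json").write_text(json.dumps(report["reporter"], indent=2))
        outputs.append("reporter/fit.json")

        # -- mechanism of action ---------------------------------------------
        moa = {}
        for grid, modality in (("dna_grid", "uncompetitive"), ("dntp_grid", "noncompetitive")):
            prog, _ = gen_progress_grid(modality, grid=grid, config=cfg)
            save_csv(prog, f"moa/progress_{grid}.csv", schema="progress")
            rates = initial_rates(prog)
            cls = classify_modality(rates)
            moa[grid] = {
                "true_modality": modality,
                "winner": cls.winner,
                "delta_aicc": cls.delta_aicc,
                "ki_nM": cls.params[cls.winner]["ki"],
            }
        report["moa"] = moa
        (workdir / "moa/moa.json").write_text(json.dumps(moa, indent=2))
        outputs.append("moa/moa.json")

        # -- DSF -------------------------------------------------------------
        melt, melt_truth = gen_melt(config=cfg)
        save_csv(melt, "dsf/melt.csv", schema="melt")
        shifts = delta_tm(melt)
        save_csv(shifts, "dsf/delta_tm.csv")
        top = shifts.sort_values("conc_nM").groupby("with_dna").tail(1)
        report["dsf"] = {
            "max_shift_plus_dna": float(top.loc[top["with_dna"], "delta_tm"].iloc[0]),
            "max_shift_minus_dna": float(top.loc[~top["with_dna"], "delta_tm"].iloc[0]),
        }
        save_csv(melt_truth, "dsf/truth.csv")

        # -- resection --------------------------------------------------------
        true_pct = np.array([5.0, 10.0, 25.0, 50.0, 80.0])
        ct, ct_truth = gen_resection(true_pct, config=cfg)
        save_csv(ct, "resection/ct.csv", schema="ct")
        res = resection_ssdna(ct["ct_digested"], ct["ct_mock"], site_id=ct["site_id"])
        save_csv(res, "resection/ssdna.csv")
        save_csv(ct_truth, "resection/truth.csv")
        report["resection"] = {
            "true_pct": true_pct.tolist(),
            "measured_pct": res["ssdna_pct"].round(2).tolist(),
        }
    except Exception:
        manifest.status = "failed"
        manifest.outputs = outputs
        manifest.write(workdir / "manifest.json")
        raise

    (workdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    outputs.append("report.json")
    lines = ["# Demo run report", "", f"seed: {seed}", ""]
    for stage, payload in report.items():
        if stage == "seed":
            continue
        lines.append(f"## {stage}")
        lines.append("```json")
        lines.append(json.dumps(payload, indent=2))
        lines.append("```")
        lines.append("")
    (workdir / "report.md").write_text("\n".join(lines))
    outputs.append("report.md")
    manifest.outputs = outputs
    manifest.write(workdir / "manifest.json")
    return report
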