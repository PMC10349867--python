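"""End-to-end orchestration: synthetic input generation, staged runs, demo.

A run directory has a fixed layout (one subdirectory per stage, CSV outputs,
and a ``manifest.json`` recording package version, parameters, per-stage
seeds and warnings).  Rerunning with an identical config and seed produces
byte-identical outputs; the manifest deliberately carries no timestamps.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from porecology import __version__, assembly, imaging, interactions
from porecology import metabolome, quantify, synth, transport

__all__ = ["write_synthetic_inputs", "run_pipeline", "demo"]

_FLOAT_FMT = "%.10g"


def _relativize(obj, root: Path):
    """Rewrite path strings relative to the run directory (for manifests)."""
    if isinstance(obj, dict):
        return {k: _relativize(v, root) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_relativize(v, root) for v in obj]
    if isinstance(obj, (str, Path)):
        try:
            return str(Path(obj).relative_to(root))
        except ValueError:
            return str(obj)
    return obj


def _write_manifest(manifest: dict, outdir: Path) -> None:
    rel = dict(manifest)
    rel["stages"] = _relativize(manifest.get("stages", {}), outdir)
    rel["config"] = _relativize(manifest.get("config", {}), outdir)
    (outdir / "manifest.json").write_text(
        json.dumps(rel, indent=2, sort_keys=True, default=str) + "\n")


def _save(df: pd.DataFrame, path: Path) -> str:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return str(path)


def _stage_seeds(seed: int, names: list[str]) -> dict[str, int]:
    """Deterministic per-stage sub-seeds fanned out from the global seed."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0]) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# synthetic input set

def write_synthetic_inputs(outdir: Path, seed: int = 0) -> dict:
    """Generate every pipeline input with ground truth under `outdir`.

    Writes TIFF scenes + grain layout, breakthrough CSVs, a qPCR standards /
    samples pair, an ASV table (TSV) + Newick tree + sample metadata, a
    co-culture yield table, and a metabolite peak table — each with a
    ground-truth CSV.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(seed, ["scenes", "curves", "qpcr", "community",
                                "coculture", "metabolites"])
    manifest: dict = {"seed": seed, "stage_seeds": seeds, "paths": {}}

    # --- grain scenes (thickness growing and roughening over time)
    scene_dir = outdir / "scenes"
    scene_dir.mkdir(exist_ok=True)
    layout_rows, truth_rows = [], []
    times = [24, 48, 72, 96]
    for k, t_h in enumerate(times):
        base = 2.0 + 0.14 * t_h
        amp = 0.05 * t_h
        spec = synth.SceneSpec(
            image_size=(220, 220),
            grain_centers=[(70, 70), (150, 150)],
            thickness=[base,
                       lambda th, a=amp, b=base: b + a * np.sin(th)],
            pixel_size=1.0,
            grain_radius=25.0,
            genus_fraction=0.7,
            noise_sd=0.02,
            seed=seeds["scenes"] + k,
        )
        scene, truth = synth.make_grain_scene(spec)
        name = f"scene_t{t_h:03d}"
        arr = np.stack([scene.channels[c] for c in sorted(scene.channels)])
        tifffile.imwrite(scene_dir / f"{name}.tif",
                         arr.astype(np.float32),
                         photometric="minisblack", planarconfig="separate",
                         metadata={"channels": sorted(scene.channels)})
        for gid, g in enumerate(scene.grains):
            layout_rows.append({"scene": name, "grain_id": gid,
                                "x_px": g.center[0], "y_px": g.center[1],
                                "radius_um": g.radius,
                                "pixel_size": scene.pixel_size,
                                "time_h": t_h})
        tg = truth.per_grain.assign(scene=name, time_h=t_h)
        if truth.genus_fractions:
            for gname, frac in truth.genus_fractions.items():
                tg[f"fraction_{gname}"] = frac
        truth_rows.append(tg)
    manifest["paths"]["layout"] = _save(pd.DataFrame(layout_rows),
                                        outdir / "layout.csv")
    manifest["paths"]["scene_truth"] = _save(pd.concat(truth_rows),
                                             outdir / "scene_truth.csv")
    manifest["paths"]["scenes"] = str(scene_dir)

    # --- breakthrough curves: pristine vs biofilm-clogged chamber
    curve_dir = outdir / "curves"
    curve_dir.mkdir(exist_ok=True)
    curve_truth = []
    for cond, mu in (("pristine", 51.5), ("colonized", 30.7)):
        for rep in range(3):
            dist = synth.GaussianPulse(mu=mu + 0.8 * rep, sigma=5.0)
            curve, truth = synth.make_breakthrough(
                dist, duration=200.0, dt=0.5, noise_sd=5e-4,
                seed=seeds["curves"] + 10 * rep + (0 if cond == "pristine"
                                                   else 1))
            path = curve_dir / f"{cond}_{rep}.csv"
            _save(pd.DataFrame({"time_min": curve.t, "signal": curve.c}),
                  path)
            curve_truth.append({"condition": cond, "replicate": rep,
                                "file": path.name,
                                "tau_analytic": truth["tau_analytic"]})
    manifest["paths"]["curves"] = str(curve_dir)
    manifest["paths"]["curve_truth"] = _save(pd.DataFrame(curve_truth),
                                             outdir / "curve_truth.csv")

    # --- qPCR standards + chamber samples along a logistic trajectory
    std, qtruth = synth.make_qpcr(efficiency=1.047, intercept=38.0,
                                  reps=3, noise_sd=0.05,
                                  seed=seeds["qpcr"])
    manifest["paths"]["qpcr_standards"] = _save(std, outdir / "qpcr_standards.csv")
    slope = qtruth["slope"]
    rngq = np.random.default_rng(seeds["qpcr"] + 1)
    sample_rows, qpcr_truth_rows = [], []
    t_h = np.array([12, 24, 36, 48, 60, 72, 84, 96], dtype=float)
    entire = 1e7 / (1.0 + np.exp(-0.12 * (t_h - 40.0)))
    plank_density = 8e5 / (1.0 + np.exp(-0.10 * (t_h - 30.0)))
    for t, c_ent, d_pl in zip(t_h, entire, plank_density):
        for comp, copies in (("entire", c_ent), ("effluent", d_pl)):
            cq = 38.0 + slope * np.log10(copies) + rngq.normal(0, 0.05)
            sample_rows.append({"chip": "chip1", "time_h": t,
                                "compartment": comp, "cq": cq})
        qpcr_truth_rows.append({"time_h": t, "c_entire": c_ent,
                                "d_planktonic": d_pl})
    manifest["paths"]["qpcr_samples"] = _save(pd.DataFrame(sample_rows),
                                              outdir / "qpcr_samples.csv")
    manifest["paths"]["qpcr_truth"] = _save(pd.DataFrame(qpcr_truth_rows),
                                            outdir / "qpcr_truth.csv")

    # --- community series (neutral + selected) as TSV/Newick/metadata
    for label, kind, strength, n_taxa in (
            ("neutral", "neutral", 0.0, 60),
            ("selected", "homogeneous_selection", 4.0, 120)):
        regime = synth.AssemblyRegime(
            kind=kind, n_taxa=n_taxa, n_samples=6,
            selection_strength=strength, n_reads=5000,
            seed=seeds["community"] + (0 if kind == "neutral" else 1),
        )
        series, _ = synth.make_community_series(regime)
        table = outdir / f"asv_{label}.tsv"
        series.abundance.rename_axis("taxon").to_csv(table, sep="\t",
                                                     float_format=_FLOAT_FMT)
        series.tree.write(path=str(outdir / f"tree_{label}.nwk"),
                          schema="newick")
        _save(pd.DataFrame({"sample": series.samples,
                            "time_h": series.sample_time}),
              outdir / f"samples_{label}.csv")
        manifest["paths"][f"asv_{label}"] = str(table)

    # --- co-culture yields
    cocult = synth.make_coculture_table(60, noise_sd=0.0,
                                        seed=seeds["coculture"])
    manifest["paths"]["coculture"] = _save(cocult, outdir / "coculture.csv")

    # --- metabolite trajectories
    shapes = ["monotone_up", "monotone_down", "v_shaped", "flat"] * 3
    specs = [synth.TrendSpec(shape=s, n_timepoints=7, noise_sd=0.0,
                             seed=seeds["metabolites"] + i)
             for i, s in enumerate(shapes)]
    peaks, labels = synth.make_metabolite_series(specs)
    manifest["paths"]["peaks"] = _save(peaks, outdir / "peaks.csv")
    manifest["paths"]["peak_truth"] = _save(labels, outdir / "peak_truth.csv")
    return manifest


# ---------------------------------------------------------------------------
# stage runners (shared by CLI subcommands and run_pipeline)

def stage_imaging(scene_dir, layout_csv, outdir: Path, *,
                  n_angles: int = 360) -> dict:
    layout = pd.read_csv(layout_csv)
    rows = []
    for scene_name, grp in layout.groupby("scene"):
        arr = tifffile.imread(Path(scene_dir) / f"{scene_name}.tif")
        with tifffile.TiffFile(Path(scene_dir) / f"{scene_name}.tif") as tf:
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        names = meta.get("channels",
                         [f"ch{i}" for i in range(arr.shape[0])])
        if arr.ndim == 2:
            arr = arr[None]
            names = ["biomass"]
        channels = dict(zip(names, arr))
        ps = float(grp["pixel_size"].iloc[0])
        grains = [imaging.GrainGeometry(center=(r.x_px, r.y_px),
                                        radius=r.radius_um)
                  for r in grp.itertuples()]
        scene = imaging.GrainScene(channels=channels, pixel_size=ps,
                                   grains=grains)
        df = imaging.analyze_scene(scene, n_angles=n_angles,
                                   scene_id=scene_name)
        if "time_h" in grp.columns:
            df["time_h"] = grp["time_h"].iloc[0]
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    return {"outputs": {"grains": _save(out, outdir / "imaging" / "grains.csv")}}


def stage_transport(curve_files, outdir: Path, *,
                    duration: float | None = None,
                    condition_of=None) -> dict:
    rows = []
    for path in sorted(map(str, curve_files)):
        curve = transport.read_curve_csv(path, duration=duration)
        tau = transport.mean_travel_time(curve)
        cond = condition_of(path) if condition_of else Path(path).stem
        rows.append({"file": Path(path).name, "condition": cond,
                     "tau_min": tau})
    df = pd.DataFrame(rows)
    outputs = {"tau": _save(df, outdir / "transport" / "tau.csv")}
    conds = df["condition"].unique()
    if len(conds) == 2:
        a = df.loc[df["condition"] == conds[0], "tau_min"]
        b = df.loc[df["condition"] == conds[1], "tau_min"]
        if len(a) >= 2 and len(b) >= 2:
            res = transport.compare_mean_travel_times(a, b)
            outputs["comparison"] = _save(
                pd.DataFrame([{"group_a": conds[0], "group_b": conds[1],
                               "difference": res.difference,
                               "statistic": res.statistic,
                               "pvalue": res.pvalue}]),
                outdir / "transport" / "comparison.csv")
    return {"outputs": outputs}


def stage_quantify(standards_csv, samples_csv, outdir: Path, *,
                   v_chip: float = quantify.DEFAULT_CHAMBER_VOLUME_UL) -> dict:
    std = pd.read_csv(standards_csv)
    curve = quantify.fit_standard_curve(std["copies"], std["cq"])
    samples = pd.read_csv(samples_csv)
    rows = []
    for (chip, t), grp in samples.groupby(["chip", "time_h"]):
        by_comp = grp.set_index("compartment")["cq"]
        c_entire = quantify.quantify(float(by_comp["entire"]), curve)
        d_plank = quantify.quantify(float(by_comp["effluent"]), curve)
        parts = quantify.partition_cells(d_plank, c_entire, v_chip)
        rows.append({"chip": chip, "time_h": t,
                     "c_planktonic": parts.c_planktonic,
                     "c_biofilm": parts.c_biofilm,
                     "c_entire": parts.c_entire,
                     "clamped": parts.clamped})
    comp = pd.DataFrame(rows).sort_values(["chip", "time_h"])
    outputs = {
        "standard_curve": _save(
            pd.DataFrame([{"slope": curve.slope,
                           "intercept": curve.intercept,
                           "r_squared": curve.r_squared,
                           "efficiency_percent": curve.efficiency_percent}]),
            outdir / "quantify" / "standard_curve.csv"),
        "compartments": _save(comp, outdir / "quantify" / "compartments.csv"),
    }
    fits = []
    for col in ("c_biofilm", "c_planktonic"):
        sub = comp[comp[col] > 0]
        if len(sub) >= 4:
            fit = quantify.fit_logistic(sub["time_h"], sub[col])
            fits.append({"series": col, "k": fit.k, "r": fit.r,
                         "t_mid": fit.t_mid, "converged": fit.converged,
                         "flag": fit.flag})
    if fits:
        outputs["logistic_fits"] = _save(pd.DataFrame(fits),
                                         outdir / "quantify" / "logistic_fits.csv")
    return {"outputs": outputs}


def stage_interactions(coculture_csv, outdir: Path,
                       conditioned_csv=None) -> dict:
    df = pd.read_csv(coculture_csv)
    calls = interactions.classify_coculture_table(df)
    outputs = {"coculture_calls": _save(
        calls, outdir / "interactions" / "coculture_calls.csv")}
    if conditioned_csv is not None:
        cond = pd.read_csv(conditioned_csv)
        out = cond.copy()
        res = [interactions.classify_conditioned(r.y_c, r.y_u)
               for r in cond.itertuples()]
        out["call"] = [c.label for c in res]
        out["margin"] = [c.margin for c in res]
        outputs["conditioned_calls"] = _save(
            out, outdir / "interactions" / "conditioned_calls.csv")
    return {"outputs": outputs}


def _read_community(table_tsv, tree_nwk, meta_csv) -> assembly.CommunitySeries:
    import dendropy

    abundance = pd.read_csv(table_tsv, sep="\t", index_col=0)
    tree = dendropy.Tree.get(path=str(tree_nwk), schema="newick")
    meta = pd.read_csv(meta_csv).set_index("sample")
    meta = meta.loc[abundance.columns]
    rep = (meta["replicate"].to_numpy() if "replicate" in meta.columns
           else None)
    return assembly.CommunitySeries(
        abundance=abundance, sample_time=meta["time_h"].to_numpy(),
        tree=tree, replicate=rep)


def stage_assembly(table_tsv, tree_nwk, meta_csv, outdir: Path, *,
                   n_null: int = 1000, seed: int = 0,
                   d_max: float = assembly.DEFAULTS["d_max"],
                   min_bin_size: int = assembly.DEFAULTS["min_bin_size"],
                   tag: str = "") -> dict:
    import warnings as _warnings

    series = _read_community(table_tsv, tree_nwk, meta_csv)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        scores = assembly.score_pairs(series, n_null=n_null, seed=seed,
                                      d_max=d_max, min_bin_size=min_bin_size)
    fractions = assembly.aggregate_processes(scores)
    trend, r, p, flag = assembly.succession_trend(
        series.abundance, series.sample_time, series.replicate)
    sub = outdir / "assembly"
    suffix = f"_{tag}" if tag else ""
    return {"outputs": {
        "scores": _save(scores, sub / f"scores{suffix}.csv"),
        "fractions": _save(pd.DataFrame([fractions]),
                           sub / f"process_fractions{suffix}.csv"),
        "succession": _save(
            trend.assign(pearson_r=r, pearson_p=p, flag=flag),
            sub / f"succession{suffix}.csv"),
    }}


def stage_metabolome(peaks_csv, outdir: Path, *,
                     features_a=None, features_b=None,
                     r_min: float = 0.5, alpha: float = 0.05,
                     n_perm: int = 999, seed: int = 0) -> dict:
    peaks = pd.read_csv(peaks_csv)
    trends = metabolome.classify_trend_table(peaks)
    sub = outdir / "metabolome"
    outputs = {"trends": _save(trends, sub / "trends.csv")}
    if features_a is not None and features_b is not None:
        fa = pd.read_csv(features_a, index_col=0)
        fb = pd.read_csv(features_b, index_col=0)
        table = metabolome.feature_correlations(fa, fb, r_min=r_min,
                                                alpha=alpha)
        outputs["correlations"] = _save(table, sub / "correlations.csv")
        shared = [s for s in fa.columns if s in set(fb.columns)]
        if len(shared) >= 3:
            from scipy.spatial.distance import pdist, squareform

            da = squareform(pdist(fa[shared].T.to_numpy(),
                                  metric="braycurtis"))
            db = squareform(pdist(fb[shared].T.to_numpy(),
                                  metric="braycurtis"))
            res = metabolome.concordance(metabolome.pcoa(da),
                                         metabolome.pcoa(db),
                                         n_perm=n_perm, seed=seed)
            outputs["concordance"] = _save(
                pd.DataFrame([{"correlation": res.correlation,
                               "m2": res.m2, "pvalue": res.pvalue,
                               "n_permutations": res.n_permutations}]),
                sub / "concordance.csv")
    return {"outputs": outputs}


# ---------------------------------------------------------------------------
# config-driven run + demo

_STAGE_ORDER = ["synth", "imaging", "transport", "quantify", "interactions",
                "assembly", "metabolome"]


def _validate_config(config: dict) -> None:
    stages = config.get("stages", {})
    unknown = set(stages) - set(_STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    path_keys = {"layout", "curves", "standards", "samples", "coculture",
                 "conditioned", "table", "tree", "meta", "peaks",
                 "scene_dir", "features_a", "features_b"}
    for name, params in stages.items():
        for key, value in (params or {}).items():
            if key in path_keys:
                values = value if isinstance(value, list) else [value]
                for v in values:
                    if not Path(v).exists():
                        raise FileNotFoundError(
                            f"stage {name!r}: missing input {v}")


def run_pipeline(config: dict, outdir) -> dict:
    """Run the enabled stages in order; returns the manifest.

    Inputs are validated up front (a missing file aborts before any stage
    runs).  A stage failure is recorded and downstream stages that consume
    its outputs are skipped; the manifest's ``status`` is then "failed".
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _validate_config(config)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", {})
    seeds = _stage_seeds(seed, _STAGE_ORDER)
    manifest = {"version": __version__, "seed": seed, "config": stages,
                "stage_seeds": {k: seeds[k] for k in stages},
                "stages": {}, "status": "ok"}
    synth_paths: dict = {}
    for name in _STAGE_ORDER:
        if name not in stages:
            continue
        params = dict(stages[name] or {})
        try:
            if name == "synth":
                res = write_synthetic_inputs(outdir / "inputs",
                                             seed=seeds["synth"])
                synth_paths = res["paths"]
                res = {"outputs": synth_paths}
            elif name == "imaging":
                res = stage_imaging(
                    params.get("scene_dir", synth_paths.get("scenes")),
                    params.get("layout", synth_paths.get("layout")),
                    outdir, n_angles=int(params.get("angles", 360)))
            elif name == "transport":
                curves = params.get("curves")
                if curves is None:
                    curves = sorted(Path(synth_paths["curves"]).glob("*.csv"))
                res = stage_transport(
                    curves, outdir, duration=params.get("duration"),
                    condition_of=lambda p: Path(p).stem.rsplit("_", 1)[0])
            elif name == "quantify":
                res = stage_quantify(
                    params.get("standards", synth_paths.get("qpcr_standards")),
                    params.get("samples", synth_paths.get("qpcr_samples")),
                    outdir, v_chip=float(params.get(
                        "vchip", quantify.DEFAULT_CHAMBER_VOLUME_UL)))
            elif name == "interactions":
                res = stage_interactions(
                    params.get("coculture", synth_paths.get("coculture")),
                    outdir, conditioned_csv=params.get("conditioned"))
            elif name == "assembly":
                tag = params.get("tag", "")
                base = Path(synth_paths.get("asv_neutral", "")).parent
                res = stage_assembly(
                    params.get("table", base / "asv_neutral.tsv"),
                    params.get("tree", base / "tree_neutral.nwk"),
                    params.get("meta", base / "samples_neutral.csv"),
                    outdir, n_null=int(params.get("nulls", 1000)),
                    seed=seeds["assembly"],
                    d_max=float(params.get("d_max",
                                           assembly.DEFAULTS["d_max"])),
                    min_bin_size=int(params.get(
                        "min_bin_size", assembly.DEFAULTS["min_bin_size"])),
                    tag=tag)
            elif name == "metabolome":
                res = stage_metabolome(
                    params.get("peaks", synth_paths.get("peaks")),
                    outdir, features_a=params.get("features_a"),
                    features_b=params.get("features_b"),
                    r_min=float(params.get("r_min", 0.5)),
                    alpha=float(params.get("alpha", 0.05)),
                    seed=seeds["metabolome"])
            manifest["stages"][name] = {"status": "ok",
                                        "outputs": res["outputs"]}
        except Exception as exc:  # noqa: BLE001 - recorded, run continues
            manifest["stages"][name] = {"status": "failed",
                                        "error": f"{type(exc).__name__}: {exc}"}
            manifest["status"] = "failed"
            if name == "synth":  # everything downstream depends on it
                for later in _STAGE_ORDER[_STAGE_ORDER.index(name) + 1:]:
                    if later in stages:
                        manifest["stages"][later] = {"status": "skipped"}
                break
    _write_manifest(manifest, outdir)
    return manifest


def demo(seed: int, outdir, *, n_null: int = 200,
         min_bin_size: int = 8) -> dict:
    """Full synthetic end-to-end run: generate all inputs, run every stage.

    Deterministic given `seed`; the run directory mirrors the study's figure
    panels (thickness/roughness series, process-fraction table, interaction
    call grid, trend clusters).  Null-model sizes are reduced to keep the
    run in the minutes range on one CPU.
    """
    outdir = Path(outdir)
    config = {
        "seed": seed,
        "stages": {
            "synth": {},
            "imaging": {"angles": 180},
            "transport": {},
            "quantify": {},
            "interactions": {},
            "assembly": {"nulls": n_null, "min_bin_size": min_bin_size},
            "metabolome": {},
        },
    }
    manifest = run_pipeline(config, outdir)
    # second assembly pass on the selected community for the panel contrast
    inputs = outdir / "inputs"
    try:
        res = stage_assembly(inputs / "asv_selected.tsv",
                             inputs / "tree_selected.nwk",
                             inputs / "samples_selected.csv",
                             outdir, n_null=n_null, min_bin_size=min_bin_size,
                             seed=manifest["stage_seeds"].get("assembly", 0),
                             tag="selected")
        manifest["stages"]["assembly_selected"] = {"status": "ok",
                                                   "outputs": res["outputs"]}
    except Exception as exc:  # noqa: BLE001
        manifest["stages"]["assembly_selected"] = {
            "status": "failed", "error": f"{type(exc).__name__}: {exc}"}
        manifest["status"] = "failed"
    _write_manifest(manifest, outdir)
    return manifest
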