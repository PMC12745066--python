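"""End-to-end attribution pipeline.

Wires the stages together the way the molar/talus analyses run them:
mirroring of right antimeres, missing-landmark estimation on group and
overall means, generalized Procrustes superimposition (with optional
semilandmark sliding), PCA and between-group PCA of the comparative
sample, projection of query reconstructions, pairwise permutation tests
with Holm adjustment, normality-gated discriminant classification with
leave-one-out cross-validation and query posteriors, geography and
MIS-group structure tests, and (optionally) radiocarbon calibration.

The configuration is a plain dict (or YAML file via the CLI); every run
writes its artifacts plus a manifest of settings and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import tpsio
from .gpa import GPA, mirror
from .radiocarbon import calibrate, collagen_metrics, read_cal_curve
from .reconstruct import estimate_missing, reconstruction_sensitivity
from .shapespace import BetweenGroupPCA, ShapePCA, scree_inflection
from .simulate import (
    make_group_means,
    outline_bulge_effect,
    outline_template,
    outline_template_coords,
    simulate_shapes,
    talus_bulge_effect,
    talus_template,
    talus_template_coords,
)
from .taxstats import (
    DiscriminantClassifier,
    chrono_group_test,
    geo_correlation,
    permutation_test_pairs,
)


class PipelineError(RuntimeError):
    def __init__(self, stage, message):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _simulate_stage(cfg, rng):
    sim = cfg["simulate"]
    kind = sim.get("kind", "outline")
    if kind == "outline":
        base = outline_template_coords()
        effect = outline_bulge_effect()
        template = outline_template()
    else:
        base = talus_template_coords()
        effect = talus_bulge_effect()
        template = talus_template()
    groups = sim["groups"]
    scale = sim.get("effect_scale", 0.06)
    # one group carries the deformation; the rest share the base shape,
    # mimicking one divergent taxon vs. several close ones
    names = list(groups)
    carrier = sim.get("effect_group",
                      "NEA" if "NEA" in groups else names[0])
    effects = {g: (effect if g == carrier else np.zeros_like(effect))
               for g in names}
    means = make_group_means(base, effects, effect_scale=scale)
    geography = sim.get("geography") or {
        g: (45.0 + 3 * i, 5.0 + 8 * i) for i, g in enumerate(names)
    }
    configs = simulate_shapes(
        means, groups, noise_sd=sim.get("noise_sd", 0.01),
        seed=int(rng.integers(2**31 - 1)), geography=geography,
    )
    return configs, template, means


def run_pipeline(config, outdir, seed=None):
    """Execute the pipeline described by ``config``; write artifacts to
    ``outdir`` and return a results dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = dict(config)
    seed = cfg.get("seed", seed) or 0
    rng = np.random.default_rng(seed)
    results = {"seed": int(seed)}

    # -- input ------------------------------------------------------------
    template = None
    if "simulate" in cfg:
        configs, template, _ = _simulate_stage(cfg, rng)
    elif "landmarks" in cfg:
        lm = cfg["landmarks"]
        configs = tpsio.read_landmarks(lm["path"], lm.get("format", "tps"))
        if lm.get("manifest"):
            tpsio.apply_manifest(configs, lm["manifest"])
    else:
        raise PipelineError("input", "config needs 'simulate' or 'landmarks'")

    # -- mirroring --------------------------------------------------------
    configs = [mirror(c) if c.side == "right" else c for c in configs]

    # -- query split ------------------------------------------------------
    qcfg = cfg.get("query", {})
    query_ids = set(qcfg.get("ids", []))
    queries = [c for c in configs if c.specimen_id in query_ids]
    sample = [c for c in configs if c.specimen_id not in query_ids]
    if "knockout_indices" in qcfg and not queries:
        # synthetic mode: hold out the last specimen as a damaged query
        queries = [sample.pop()]
        idx = np.asarray(qcfg["knockout_indices"], dtype=int)
        for q in queries:
            q.present[idx] = False

    # -- reconstruction references ---------------------------------------
    try:
        labels = np.array([c.group for c in sample])
        shapes_in = sample
        complete = [c for c in sample if c.is_complete]
        if len(complete) < len(sample):
            overall_ref = np.stack([c.coords for c in complete]).mean(axis=0)
            shapes_in = [c if c.is_complete else estimate_missing(c, overall_ref)
                         for c in sample]
    except Exception as exc:
        raise PipelineError("reconstruction", str(exc)) from exc

    # -- GPA --------------------------------------------------------------
    try:
        gcfg = cfg.get("gpa", {})
        est = GPA(scale=gcfg.get("scale", True),
                  slide=gcfg.get("slide", False), template=template)
        est.fit(shapes_in)
    except Exception as exc:
        raise PipelineError("gpa", str(exc)) from exc
    aligned = est.to_dataset()

    # -- shape space ------------------------------------------------------
    space = ShapePCA().fit(aligned.shapes)
    var = space.explained_variance_ratio_
    results["variance_fraction_pc1_3"] = float(var[:3].sum())
    results["scree_elbow"] = int(scree_inflection(var)) if var.size >= 3 else None
    pd.DataFrame({"variance_fraction": var}).to_csv(
        outdir / "variance.csv", index=False)
    tpsio.write_scores_csv(space.scores_, outdir / "scores.csv",
                           labels=labels,
                           specimen_ids=[c.specimen_id for c in sample])

    # -- query reconstruction + projection --------------------------------
    group_means = {}
    for g in np.unique(labels):
        group_means[g] = aligned.shapes[labels == g].mean(axis=0)
    group_means["overall"] = aligned.consensus
    query_scores = {}
    sensitivity = {}
    for q in queries:
        try:
            if q.is_complete:
                completed = q
            else:
                # scale references back to raw-ish units via OPA inside
                completed = estimate_missing(
                    q, _mean_in_raw_units(group_means["overall"], q))
            aligned_q = est.transform(completed.coords)
            query_scores[q.specimen_id] = space.transform(aligned_q[None])[0]
            if not q.is_complete:
                refs = {g: _mean_in_raw_units(m, q)
                        for g, m in group_means.items()}
                table, dist = reconstruction_sensitivity(
                    q, refs, _SpaceOnAligned(est, space))
                sensitivity[q.specimen_id] = {
                    "scores": table, "max_pairwise": float(dist.to_numpy().max()),
                }
                table.to_csv(outdir / f"sensitivity_{q.specimen_id}.csv")
        except Exception as exc:
            raise PipelineError(
                "projection", f"specimen {q.specimen_id!r}: {exc}") from exc

    # -- permutation tests ------------------------------------------------
    ncfg = cfg.get("permutation", {})
    perm = permutation_test_pairs(
        space.scores_[:, :3], labels,
        n_permutations=ncfg.get("n", 10000),
        rng=int(rng.integers(2**31 - 1)),
    )
    perm.to_frame().to_csv(outdir / "permutation.csv", index=False)
    results["permutation_min_p_holm"] = float(perm.p_holm.min())

    # -- discriminant analysis -------------------------------------------
    dcfg = cfg.get("da", {})
    pooled = dcfg.get("pool_sapiens", True)
    da_labels = labels.copy()
    if pooled and "NEA" in labels:
        da_labels = np.where(labels == "NEA", "NEA", "HS")
    clf = DiscriminantClassifier(model=dcfg.get("model", "auto"),
                                 n_pcs=dcfg.get("n_pcs"))
    clf.fit(space.scores_, da_labels, variance_ratio=var)
    qnames = list(query_scores)
    qscores = (np.stack([query_scores[n] for n in qnames])
               if qnames else None)
    report = clf.report(qscores, qnames)
    results["da_model"] = report.model
    results["da_pcs_used"] = int(report.pcs_used)
    results["da_loo_accuracy"] = float(report.loo_accuracy)
    report.confusion.to_csv(outdir / "confusion.csv")
    if report.query_posteriors is not None:
        report.query_posteriors.to_csv(outdir / "query_posteriors.csv")
        results["query_posteriors"] = {
            n: dict(zip(report.query_posteriors.columns,
                        map(float, report.query_posteriors.loc[n])))
            for n in qnames
        }

    # -- between-group PCA -----------------------------------------------
    bg = BetweenGroupPCA().fit(aligned.shapes, labels)
    tpsio.write_scores_csv(bg.scores_, outdir / "bg_scores.csv",
                           labels=labels, prefix="bgPC",
                           specimen_ids=[c.specimen_id for c in sample])
    results["bg_n_axes"] = int(bg.components_.shape[0])

    # -- geography / chronology ------------------------------------------
    geo_group = cfg.get("geo_group", "NEA")
    sel = labels == geo_group
    meta = [c.meta for c in sample]
    if sel.sum() >= 4 and all("latitude" in m for m, s in zip(meta, sel) if s):
        lats = [m["latitude"] for m, s in zip(meta, sel) if s]
        lons = [m["longitude"] for m, s in zip(meta, sel) if s]
        geo = geo_correlation(space.scores_[sel, :3], lats, lons)
        geo.to_csv(outdir / "geo_correlation.csv", index=False)
        mis = np.array([m.get("mis_group", "") for m, s in zip(meta, sel) if s])
        if len(set(mis)) == 2 and min(np.bincount(pd.factorize(mis)[0])) >= 3:
            chrono = chrono_group_test(space.scores_[sel, :3], mis)
            chrono.to_csv(outdir / "chrono_test.csv", index=False)

    # -- radiocarbon ------------------------------------------------------
    if "calibration" in cfg:
        ccfg = cfg["calibration"]
        curve = read_cal_curve(ccfg["curve"])
        cal_out = {}
        for s in ccfg.get("samples", []):
            post = calibrate(s["age_14c"], s["sigma"], curve)
            entry = {"rendered_95": post.render_bc_ad(0.954),
                     "rendered_68": post.render_bc_ad(0.682)}
            if all(k in s for k in ("sample_mg", "collagen_mg", "pctC", "pctN")):
                y, cn, flags = collagen_metrics(
                    s["sample_mg"], s["collagen_mg"], s["pctC"], s["pctN"])
                entry.update({"yield_pct": y, "cn_atomic": cn,
                              "qc_pass": flags["pass"]})
            cal_out[s["name"]] = entry
        results["calibration"] = cal_out

    # -- provenance -------------------------------------------------------
    manifest = {"settings": _jsonable(cfg), "seed": int(seed),
                "n_specimens": len(sample), "n_queries": len(queries),
                "gpa_iterations": int(aligned.iterations),
                "gpa_converged": bool(aligned.converged)}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (outdir / "results.json").write_text(json.dumps(_jsonable(results),
                                                    indent=2))
    return results


class _SpaceOnAligned:
    """Adapter: align raw coordinates to the GPA consensus before
    projecting into the PCA space (for sensitivity tables)."""

    def __init__(self, gpa_est, space):
        self.gpa = gpa_est
        self.space = space

    def transform(self, coords):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        aligned = self.gpa.transform(coords)
        return self.space.transform(aligned)


def _mean_in_raw_units(mean_shape, config):
    """Scale a unit-CS mean up to the specimen's rough size so the TPS in
    estimate_missing operates at comparable magnitudes (it re-superimposes
    internally; this only conditions the system)."""
    from .gpa import centroid_size

    cs = centroid_size(config.coords[config.present])
    return mean_shape * max(cs, 1.0)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict()
    return obj
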