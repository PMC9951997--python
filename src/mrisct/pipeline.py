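"""Experiment orchestration: data generation, training, prediction, reports.

``run_experiment`` drives the whole workflow on synthetic phantom pairs for
either of the two mask scenarios: ``ct_masks`` (tissue masks derived from the
conditioned CT, isolating translation quality) and ``mri_only`` (masks derived
from the MRI-side anatomy, emulating an MRI-only treatment workflow where no
CT exists).  Every random element is seeded from one master seed and all
reports are plain CSV, so a repeated run is byte-identical.
"""

from __future__ import annotations

import csv
import json
import time

from pathlib import Path

import numpy as np
import yaml

from . import cgan, doseeval, evaluate, phantom, preprocess
from .preprocess import CHANNEL_NAMES, ChannelRanges
from .volume import ImageVolume, write_nifti


# ---------------------------------------------------------------------------
# cross-validation folds
# ---------------------------------------------------------------------------

def make_folds(
    volume_ids: list,
    k: int = 6,
    seed: int = 0,
    subject_of: dict | None = None,
) -> dict:
    """Assign volume ids to ``k`` disjoint folds of near-equal size.

    Volumes sharing a subject (re-evaluative acquisitions) are kept in the
    same fold.  Subjects are shuffled deterministically and greedily assigned
    to the currently smallest fold, so singleton subjects give fold sizes
    differing by at most one.
    """
    ids = list(volume_ids)
    if k < 1:
        raise ValueError("k must be >= 1")
    subject_of = subject_of or {v: v for v in ids}
    groups: dict = {}
    for v in ids:
        groups.setdefault(subject_of[v], []).append(v)
    if len(groups) < k:
        raise ValueError(f"{len(groups)} subjects cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    subjects = sorted(groups)
    rng.shuffle(subjects)
    # largest groups first, then greedy into the smallest fold
    subjects.sort(key=lambda s: -len(groups[s]))
    folds: list[list] = [[] for _ in range(k)]
    for s in subjects:
        smallest = min(range(k), key=lambda i: (len(folds[i]), i))
        folds[smallest].extend(groups[s])
    return {v: i for i, fold in enumerate(folds) for v in fold}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "seed": 0,
    "scenario": "ct_masks",
    "phantom": {
        "grid_shape": [32, 96, 96],
        "spacing": [3.0, 2.0, 2.0],
        "n_train": 2,
        "n_test": 1,
        "jitter_mm": 5.0,
        "mismatch": None,  # e.g. {structure, displacement_mm, volume_scale}
    },
    "preprocess": {
        "net_size": 64,
        "augment": False,
        "max_slices_per_volume": 16,
    },
    "model": {
        "tiny": True,
        "epochs": 2,
    },
    "dose": {
        "beam": {
            "entry_mm": [48.0, 0.0, 98.0],
            "direction": [0.0, 1.0, 0.0],
            "nominal_range_mm": 95.0,
            "prescription_dose": 40.0,
        },
        "gamma_criteria": [[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]],
        "thresholds": [10.0, 50.0, 90.0],
        "subvoxel": False,
        "n_rs_slices": 10,
    },
    "evaluate": {
        "tost_margin_pct": 0.5,
    },
    "save_volumes": False,
}


def load_config(path: str | Path | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(cfg, user)
    return cfg


def _deep_update(base: dict, extra: dict) -> None:
    for key, val in extra.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            _deep_update(base[key], val)
        else:
            base[key] = val


def _child_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def _phantom_spec(cfg: dict, seed: int, jitter_mm: float) -> phantom.PhantomSpec:
    spec = phantom.PhantomSpec(
        grid_shape=tuple(cfg["grid_shape"]),
        spacing=tuple(cfg["spacing"]),
        seed=seed,
    )
    if jitter_mm > 0:
        spec = spec.jittered(seed, magnitude_mm=jitter_mm)
    return spec


def _conditioned_pair(spec, mri_reference=None, mismatch=None):
    ct, mri, labels = phantom.generate_pair(spec)
    mri_labels = labels
    if mismatch is not None:
        m = phantom.MismatchSpec(
            structure=mismatch["structure"],
            displacement_mm=tuple(mismatch.get("displacement_mm", (0, 0, 0))),
            volume_scale=float(mismatch.get("volume_scale", 1.0)),
        )
        mri, mri_labels = phantom.apply_mismatch(mri, labels, spec, m)
    ct_c = preprocess.prepare_ct(ct, mri)
    mri_c = preprocess.prepare_mri(mri, reference=mri_reference)
    return ct_c, mri_c, labels, mri_labels, spec


def _training_triplets(ct_c, mri_c, net_size, max_slices, augment, aug_seed):
    ranges = ChannelRanges()
    ct_masks3d = ranges.masks(ct_c.values, ct_c.body_mask)
    ct_trips = preprocess.segment_channels(ct_c)
    mri_trips = preprocess.segment_channels(mri_c, masks=ct_masks3d)
    pairs = []
    for mri_t, ct_t in zip(mri_trips, ct_trips):
        if not ct_t.body_mask.any():
            continue
        m = preprocess.resize_to_net(preprocess.scale_channels(mri_t, "to_unit"), net_size)
        c = preprocess.resize_to_net(preprocess.scale_channels(ct_t, "to_unit"), net_size)
        pairs.append((m, c))
    if max_slices and len(pairs) > max_slices:
        idx = np.linspace(0, len(pairs) - 1, max_slices).round().astype(int)
        pairs = [pairs[i] for i in idx]
    if augment:
        spec = preprocess.AugmentationSpec(seed=aug_seed)
        out = []
        for p in pairs:
            out.extend(augment_to_pairs(p, spec))
        pairs = out
    return pairs


def augment_to_pairs(pair, spec):
    # augment_pair works on (mri, ct) triplets directly
    return preprocess.augment_pair(pair, spec)


def masks_from_labels(labels: ImageVolume, organs) -> dict[str, np.ndarray]:
    """Tissue-class masks from an organ label map (the 'manual segmentation')."""
    lab = labels.values.astype(int)
    masks = {n: np.zeros(lab.shape, dtype=bool) for n in CHANNEL_NAMES}
    for o in organs:
        masks[o.tissue] |= lab == o.label
    return masks


# ---------------------------------------------------------------------------
# CSV helpers (stable formatting for byte-identical reruns)
# ---------------------------------------------------------------------------

def _fmt(v):
    if isinstance(v, float):
        return f"{v:.10g}"
    return v


def write_csv(path: Path, fieldnames: list[str], rows: list[dict]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=fieldnames)
        w.writeheader()
        for row in rows:
            w.writerow({k: _fmt(row.get(k, "")) for k in fieldnames})


# ---------------------------------------------------------------------------
# the experiment
# ---------------------------------------------------------------------------

def run_experiment(config: dict | str | Path | None, outdir: str | Path) -> dict:
    """Run the full workflow and write the report bundle to ``outdir``.

    Returns a dict with the in-memory results (reports and summary values).
    Reports: similarity.csv, geometry.csv, dvh.csv, tost.csv, gamma.csv,
    rs_records.csv, range_shift_summary.csv, training_log.csv,
    provenance.json.
    """
    t0 = time.time()
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = config
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenario = cfg["scenario"]
    if scenario not in ("ct_masks", "mri_only"):
        raise ValueError(f"unknown scenario {scenario!r}")

    master = int(cfg["seed"])
    pcfg = cfg["phantom"]
    n_train, n_test = int(pcfg["n_train"]), int(pcfg["n_test"])
    seeds = _child_seeds(master, n_train + n_test + 2)
    train_seeds, test_seeds = seeds[:n_train], seeds[n_train:n_train + n_test]
    aug_seed, model_seed = seeds[-2], seeds[-1]

    # --- training data ---
    net_size = int(cfg["preprocess"]["net_size"])
    dataset = []
    mri_reference = None
    for s in train_seeds:
        spec = _phantom_spec(pcfg, s, pcfg["jitter_mm"])
        ct_c, mri_c, *_ = _conditioned_pair(spec, mri_reference=mri_reference)
        if mri_reference is None:
            mri_reference = mri_c  # histogram-matching template: first volume
        dataset.extend(_training_triplets(
            ct_c, mri_c, net_size, cfg["preprocess"]["max_slices_per_volume"],
            cfg["preprocess"]["augment"], aug_seed,
        ))

    # --- model ---
    mcfg = dict(cfg["model"])
    tiny = mcfg.pop("tiny", True)
    mcfg["seed"] = model_seed
    mcfg.setdefault("size", net_size)
    gan_config = cgan.GanConfig.tiny(**mcfg) if tiny else cgan.GanConfig(**mcfg)
    state = cgan.train(dataset, gan_config,
                       progress_csv=outdir / "training_log.csv")
    cgan.save_checkpoint(state, outdir / "model.npz")

    # --- test volumes ---
    sim_rows, geo_rows, dvh_rows, gamma_rows, rs_rows = [], [], [], [], []
    rs_summaries = []
    d95_ct, d95_sct = [], []
    dcfg = cfg["dose"]
    beam = phantom.BeamSpec(
        entry_mm=tuple(dcfg["beam"]["entry_mm"]),
        direction=tuple(dcfg["beam"]["direction"]),
        nominal_range_mm=float(dcfg["beam"]["nominal_range_mm"]),
        prescription_dose=float(dcfg["beam"]["prescription_dose"]),
    )
    ranges = ChannelRanges()
    for vol_id, s in enumerate(test_seeds):
        spec = _phantom_spec(pcfg, s, pcfg["jitter_mm"])
        ct_c, mri_c, ct_labels, mri_labels, spec = _conditioned_pair(
            spec, mri_reference=mri_reference, mismatch=pcfg["mismatch"],
        )
        ct_masks3d = ranges.masks(ct_c.values, ct_c.body_mask)
        if scenario == "ct_masks":
            masks = ct_masks3d
        else:
            masks = masks_from_labels(mri_labels, spec.organs)
        sct = cgan.predict_volume(state, mri_c, masks)

        if cfg.get("save_volumes"):
            write_nifti(ct_c, outdir / f"ct_{vol_id}.nii.gz")
            write_nifti(mri_c, outdir / f"mri_{vol_id}.nii.gz")
            write_nifti(sct, outdir / f"sct_{vol_id}.nii.gz")

        # similarity per region (CT-based regions, background excluded)
        regions = {"body": ct_c.body_mask, **ct_masks3d}
        report = evaluate.similarity(sct, ct_c, regions)
        for region, m in report.regions.items():
            sim_rows.append({
                "volume": vol_id, "region": region, "mae": m.mae, "rmse": m.rmse,
                "ncc": m.ncc, "ssim": m.ssim, "psnr": m.psnr,
            })

        # geometry: air pockets (thresholdable on sCT) and kidneys (labels)
        sct_air = sct.body_mask & (sct.values < ranges.air[1])
        ct_air = ct_masks3d["air"]
        mri_air = masks_from_labels(mri_labels, spec.organs)["air"]
        geo_pairs = {
            ("air", "ct_mri"): (ct_air, mri_air),
            ("air", "sct_ct"): (sct_air, ct_air),
            ("air", "sct_mri"): (sct_air, mri_air),
        }
        kid_ct = np.isin(ct_labels.values, [5, 6])
        kid_mri = np.isin(mri_labels.values, [5, 6])
        if kid_ct.any() and kid_mri.any():
            geo_pairs[("kidneys", "ct_mri")] = (kid_ct, kid_mri)
        for (structure, pair_name), (ma, mb) in geo_pairs.items():
            if not ma.any() or not mb.any():
                continue
            g = evaluate.geometry(ma, mb, ct_c.spacing)
            geo_rows.append({
                "volume": vol_id, "structure": structure, "pair": pair_name,
                "dsc": g.dsc, "hd95_mm": g.hd95_mm, "comd_mm": g.comd_mm,
            })

        # dose: toy engine on CT and sCT, same beam
        dose_ct = doseeval.DoseGrid(phantom.toy_dose(ct_c, beam), beam.prescription_dose)
        dose_sct = doseeval.DoseGrid(phantom.toy_dose(sct, beam), beam.prescription_dose)
        gtv = ct_labels.values == 9  # tumor label
        oars = {"kidneys": kid_ct}
        if gtv.any():
            c_ct = doseeval.dvh_d(dose_ct, gtv, "D95")
            c_sct = doseeval.dvh_d(dose_sct, gtv, "D95")
            d95_ct.append(c_ct)
            d95_sct.append(c_sct)
            dvh_rows.append({"volume": vol_id, "structure": "gtv", "metric": "D95",
                             "ct": c_ct, "sct": c_sct, "diff": c_sct - c_ct})
        for name, m in oars.items():
            if m.any():
                c_ct = doseeval.dvh_d(dose_ct, m, "D2")
                c_sct = doseeval.dvh_d(dose_sct, m, "D2")
                dvh_rows.append({"volume": vol_id, "structure": name, "metric": "D2",
                                 "ct": c_ct, "sct": c_sct, "diff": c_sct - c_ct})

        for tol, dta in dcfg["gamma_criteria"]:
            for thr in dcfg["thresholds"]:
                crit = doseeval.GammaCriteria(float(tol), float(dta), float(thr))
                rate = doseeval.gamma_pass_rate(dose_ct, dose_sct, crit,
                                                subvoxel=bool(dcfg["subvoxel"]))
                gamma_rows.append({"volume": vol_id, "dose_tol_pct": tol,
                                   "dta_mm": dta, "threshold_pct": thr,
                                   "pass_rate_pct": rate})

        records, summary = doseeval.range_shift(
            dose_ct, dose_sct, beam, n_slices=int(dcfg["n_rs_slices"]),
            target_mask=gtv if gtv.any() else None,
        )
        for r in records:
            rs_rows.append({"volume": vol_id, "slice": r.slice_index,
                            "r_ct80_mm": r.r_ref80_mm, "r_sct80_mm": r.r_eval80_mm,
                            "rs_mm": r.rs_mm, "rrs": r.rrs,
                            "flagged": int(r.flagged), "valid": int(r.valid)})
        rs_summaries.append({"volume": vol_id, **summary})

    # TOST-P on the paired GTV D95 values (margin: % of prescription)
    tost_rows = []
    if len(d95_ct) >= 3:
        margin = cfg["evaluate"]["tost_margin_pct"] / 100.0 * beam.prescription_dose
        res = evaluate.tost_paired(np.array(d95_sct), np.array(d95_ct), margin)
        tost_rows.append({
            "metric": "gtv_D95", "n": res.n, "mean_diff": res.mean_diff,
            "margin": res.margin, "p_lower": res.p_lower, "p_upper": res.p_upper,
            "equivalent": int(res.equivalent),
        })

    write_csv(outdir / "similarity.csv",
              ["volume", "region", "mae", "rmse", "ncc", "ssim", "psnr"], sim_rows)
    write_csv(outdir / "geometry.csv",
              ["volume", "structure", "pair", "dsc", "hd95_mm", "comd_mm"], geo_rows)
    write_csv(outdir / "dvh.csv",
              ["volume", "structure", "metric", "ct", "sct", "diff"], dvh_rows)
    write_csv(outdir / "tost.csv",
              ["metric", "n", "mean_diff", "margin", "p_lower", "p_upper",
               "equivalent"], tost_rows)
    write_csv(outdir / "gamma.csv",
              ["volume", "dose_tol_pct", "dta_mm", "threshold_pct",
               "pass_rate_pct"], gamma_rows)
    write_csv(outdir / "rs_records.csv",
              ["volume", "slice", "r_ct80_mm", "r_sct80_mm", "rs_mm", "rrs",
               "flagged", "valid"], rs_rows)
    write_csv(outdir / "range_shift_summary.csv",
              ["volume", "median_rs_mm", "iqr_rs_mm", "n_valid", "n_flagged",
               "n_invalid"], rs_summaries)

    provenance = {
        "config": cfg,
        "seeds": {"master": master, "train": train_seeds, "test": test_seeds,
                  "augment": aug_seed, "model": model_seed},
        "n_training_pairs": len(dataset),
        "gan_parameters": state.n_parameters,
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    with open(outdir / "runlog.txt", "w") as fh:
        fh.write(f"elapsed_s {time.time() - t0:.1f}\n")

    return {
        "similarity": sim_rows, "geometry": geo_rows, "dvh": dvh_rows,
        "tost": tost_rows, "gamma": gamma_rows, "rs_records": rs_rows,
        "rs_summaries": rs_summaries, "n_training_pairs": len(dataset),
    }
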