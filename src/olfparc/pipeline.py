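"""End-to-end workflow: simulate/load -> preprocess -> connectivity ->
stability -> parcellation -> per-cluster group maps -> network decomposition.

Every stage logs its parameters and timing; the final provenance report
records all parameters, seeds, package versions and per-stage checksums so
any output file is reproducible from the config alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import __version__
from .connectivity import group_average, loo_stability, stability_threshold, voxelwise_connectivity
from .groupstats import TFCEParams, seed_zmap, signflip_ttest, unique_common_masks
from .io import PipelineConfig, read_nifti, write_nifti, write_table
from .parcellation import k_sweep, kmeans_correlation, match_clusters, overlap_proportions, permutation_zscore
from .preprocess import NuisanceSet, preprocess_bold
from .synthetic import SyntheticSpec, generate_dataset
from .volume import Bold4D, mask_coordinates

log = logging.getLogger("olfparc")


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis described by ``config``; returns the report.

    Any stage failure aborts with the stage name and the offending input in
    the exception message.
    """
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": json.loads(config.to_json()),
                    "stages": {}}

    def stage(name):
        log.info("stage %s", name)
        report["stages"][name] = {"t_start": time.time() - t0}
        return name

    # ---- inputs -----------------------------------------------------------
    name = stage("inputs")
    truth_roi = None
    try:
        if config.simulate:
            spec = SyntheticSpec(rng_seed=config.rng_seed)
            ds = generate_dataset(spec)
            bolds = ds.bolds
            brain_mask, seed_mask, anat_vol = ds.brain_mask, ds.seed_mask, ds.anat_labels
            coords = mask_coordinates(seed_mask)
            truth_roi = ds.truth_labels[coords[:, 0], coords[:, 1], coords[:, 2]]
            affine = spec.affine
        else:
            bolds = []
            for p in config.bold_paths:
                data, affine = read_nifti(p, expect_ndim=4)
                bolds.append(Bold4D(data, affine))
            brain_mask, _ = read_nifti(config.brain_mask_path, expect_ndim=3)
            seed_mask, _ = read_nifti(config.seed_mask_path, expect_ndim=3)
            anat_vol, _ = read_nifti(config.anat_labels_path, expect_ndim=3)
            brain_mask = brain_mask.astype(bool)
            seed_mask = seed_mask.astype(bool)
    except Exception as exc:
        raise RuntimeError(f"stage {name} failed: {exc}") from exc

    # ---- preprocessing ----------------------------------------------------
    name = stage("preprocess")
    try:
        nuisances = [NuisanceSet.from_text(p) for p in config.nuisance_paths] or None
        clean = []
        for i, b in enumerate(bolds):
            nuis = nuisances[i] if nuisances else None
            clean.append(preprocess_bold(
                b, nuisance=nuis, detrend_order=config.detrend_order,
                low_hz=config.low_hz, high_hz=config.high_hz,
                sigma_mm=config.sigma_mm, drop_frames=config.drop_frames,
            ))
    except Exception as exc:
        raise RuntimeError(f"stage {name} failed: {exc}") from exc

    # ---- connectivity + stability ----------------------------------------
    name = stage("connectivity")
    try:
        mats = [voxelwise_connectivity(b, seed_mask, brain_mask, subject_id=str(i))
                for i, b in enumerate(clean)]
        group = group_average(mats)
        stability = loo_stability(mats)
        r_crit = stability_threshold(len(group.target_index), len(group.roi_index))
        stab_vol = np.zeros(brain_mask.shape)
        coords = group.roi_index
        stab_vol[coords[:, 0], coords[:, 1], coords[:, 2]] = stability
        write_nifti(stab_vol, affine, out / "stability_map.nii")
        report["stages"][name].update(
            stability_mean=float(stability.mean()),
            stability_min=float(stability.min()),
            stability_r_threshold=r_crit,
            checksum=_checksum(group.values),
        )
    except Exception as exc:
        raise RuntimeError(f"stage {name} failed: {exc}") from exc

    # ---- parcellation -----------------------------------------------------
    name = stage("parcellation")
    try:
        anat_roi = anat_vol[coords[:, 0], coords[:, 1], coords[:, 2]].astype(np.int32)
        parc = kmeans_correlation(group, config.k, n_init=config.n_init,
                                  rng_seed=config.rng_seed)
        table = overlap_proportions(parc, anat_roi)
        table = permutation_zscore(table, parc, anat_roi,
                                   n_perm=config.n_perm_parcel, rng_seed=config.rng_seed)
        mapping = match_clusters(parc, anat_roi)
        label_vol = np.zeros(brain_mask.shape, dtype=np.int32)
        label_vol[coords[:, 0], coords[:, 1], coords[:, 2]] = parc.labels
        write_nifti(label_vol, affine, out / f"parcellation_k{config.k}.nii")
        write_table(table.to_dataframe(), out / f"overlap_k{config.k}.tsv")
        info = {"k": config.k, "mapping": mapping,
                "min_matched_z": float(min(table.z_scores[c - 1, r - 1]
                                           for c, r in mapping.items())),
                "q_sig_regions_per_cluster": (table.fdr_q < 0.001).sum(axis=1).tolist(),
                "checksum": _checksum(parc.labels)}
        if truth_roi is not None:
            info["ari"] = float(adjusted_rand_score(truth_roi, parc.labels))
        report["stages"][name].update(info)
        if config.k_sweep:
            sweep = k_sweep(group, anat_roi, ks=config.k_sweep, n_init=config.n_init,
                            n_perm=config.n_perm_parcel, rng_seed=config.rng_seed)
            for kk, (pk, tk) in sweep.items():
                lv = np.zeros(brain_mask.shape, dtype=np.int32)
                lv[coords[:, 0], coords[:, 1], coords[:, 2]] = pk.labels
                write_nifti(lv, affine, out / f"parcellation_k{kk}.nii")
                write_table(tk.to_dataframe(), out / f"overlap_k{kk}.tsv")
            report["stages"][name]["k_sweep"] = {
                kk: float(pk.total_within_cluster_distance) for kk, (pk, tk) in sweep.items()
            }
    except Exception as exc:
        raise RuntimeError(f"stage {name} failed: {exc}") from exc

    # ---- per-cluster group maps ------------------------------------------
    name = stage("group_maps")
    try:
        params = TFCEParams(E=config.tfce_E, H=config.tfce_H,
                            n_steps=config.tfce_steps,
                            connectivity_neighbourhood=config.tfce_neighbourhood)
        results = {}
        for c in range(1, config.k + 1):
            cmask = np.zeros(brain_mask.shape, dtype=bool)
            sel = coords[parc.labels == c]
            cmask[sel[:, 0], sel[:, 1], sel[:, 2]] = True
            zmaps = [seed_zmap(b, cmask, brain_mask, subject_id=str(i))
                     for i, b in enumerate(clean)]
            res = signflip_ttest(zmaps, params, n_perm=config.n_perm_group,
                                 alpha=config.alpha, rng_seed=config.rng_seed)
            results[f"cluster_{c}"] = res
            write_nifti(res.sig_mask, affine, out / f"sigmask_cluster{c}.nii")
        unique, common = unique_common_masks(results)
        for nm, m in unique.items():
            write_nifti(m, affine, out / f"unique_{nm}.nii")
        write_nifti(common, affine, out / "common_mask.nii")
        report["stages"][name].update(
            n_sig={nm: int(r.sig_mask.sum()) for nm, r in results.items()},
            n_common=int(common.sum()),
        )
    except Exception as exc:
        raise RuntimeError(f"stage {name} failed: {exc}") from exc

    report["runtime_s"] = time.time() - t0
    (out / "provenance.json").write_text(json.dumps(report, indent=1, default=str))
    return report
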