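"""End-to-end study orchestration.

``run_study`` reproduces the full analysis on one study bundle (real or
synthetic): per-image partition of participants into successful /
underperforming clinicians and non-clinicians, common-attention
subtraction, subgroup averaging, smoothing, dual noise thresholds,
occlusion saliency with ensemble averaging and coverage matching,
IoU/KL comparisons with participant bootstrap SDs, random-effects
pooling per pair and threshold level, response accuracy and chi-square
tables, and an exclusion log that accounts for every skipped cell.

Comparison pairs (side A is the bootstrap-resampled side):

* ``clin_vs_saliency``  — successful clinicians vs the coverage-matched
  ensemble saliency map, affected images, both levels;
* ``clin_vs_nonclin``   — successful clinicians vs successful
  non-clinicians, all images, both levels, no coverage matching (human
  groups may legitimately differ in coverage);
* ``success_vs_under``  — successful vs underperforming participants
  within each group, low level;
* ``self_consistency``  — per participant, average attention on affected
  vs unaffected images, low level.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .maps import (AttentionMap, FaceMask, FixationEvent, IntensityGrid,
                   ThresholdSpec, average_maps, render_from_fixations, smooth,
                   apply_noise_threshold)
from .metrics import (AOIRegion, ComparisonResult, aoi_metrics, bootstrap_sds_both,
                      iou, symmetric_kl)
from .saliency import (OcclusionConfig, PrototypeClassifier, SaliencyMap,
                       UnreliableSaliencyError, coverage_cutoff, ensemble_saliency,
                       match_coverage, saliency_at_resolution)
from .stats import ResponseRecord, accuracy_table, chi_square_2x2, random_effects_pool
from .synthetic import ToyStudy, generate_toy_study

__all__ = ["StudyParams", "StudyConfig", "run_study", "run_study_from_dir",
           "save_study", "load_study", "simulate_to_dir"]

GROUPS = ("clinician", "nonclinician")


@dataclass
class StudyParams:
    """Analysis knobs shared by every stage."""

    low_mode: str = "coverage_fraction"
    low_value: float = 0.07
    high_mode: str = "coverage_fraction"
    high_value: float = 0.035
    smooth_kernel: int = 15
    occlusion_box: int = 20
    occlusion_stride: int = 10
    bootstrap_B: int = 100
    kl_eps: Optional[float] = None
    seed: int = 0
    radius: int = 25
    min_subgroup: int = 2
    pairs: tuple[str, ...] = ("clin_vs_saliency", "clin_vs_nonclin",
                              "success_vs_under", "self_consistency")

    def threshold(self, level: str) -> ThresholdSpec:
        if level == "low":
            return ThresholdSpec(self.low_mode, self.low_value)
        return ThresholdSpec(self.high_mode, self.high_value)

    def occlusion(self) -> OcclusionConfig:
        return OcclusionConfig(box=self.occlusion_box, stride=self.occlusion_stride)


@dataclass
class StudyConfig:
    """File-level study description consumed by the CLI verbs."""

    study_dir: Path
    out_dir: Path
    params: StudyParams = field(default_factory=StudyParams)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text())
        params = StudyParams(**data.get("params", {}))
        if isinstance(params.pairs, list):
            params.pairs = tuple(params.pairs)
        return cls(study_dir=Path(data["study_dir"]), out_dir=Path(data["out_dir"]),
                   params=params)

    def to_yaml(self, path) -> None:
        data = {"study_dir": str(self.study_dir), "out_dir": str(self.out_dir),
                "params": {**asdict(self.params), "pairs": list(self.params.pairs)}}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


# -- study serialization ------------------------------------------------------

def save_study(study: ToyStudy, directory) -> Path:
    """Write a synthetic study bundle in the exact formats the pipeline reads."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    gio.write_fixations(d / "fixations.csv", study.cohort.fixations)
    gio.write_responses(d / "responses.csv", study.cohort.responses)
    gio.write_mask_png(d / "mask.png", study.mask)
    gio.write_aois(d / "aois.json", study.aois)

    img_dir = d / "images"
    img_dir.mkdir(exist_ok=True)
    img_rows = []
    for image_id in study.cohort.image_ids:
        fn = f"{image_id}.png"
        scale = gio.write_map_png(img_dir / fn, study.images[image_id])
        img_rows.append({"filename": fn, "participant_id": "", "group": "",
                         "image_id": image_id, "stage": "raw", "scale": scale})
    gio.write_manifest(img_dir / "manifest.csv", img_rows)

    for k, clf in enumerate(study.classifiers):
        cdir = d / "classifiers" / f"model_{k}"
        cdir.mkdir(parents=True, exist_ok=True)
        scales = {}
        for lab in clf.labels:
            proto = clf._protos[list(clf.labels).index(lab)]
            scales[lab] = gio.write_map_png(cdir / f"{lab}.png", proto)
        meta = {"labels": list(clf.labels), "temperature": clf.temperature,
                "scales": scales}
        (cdir / "meta.json").write_text(json.dumps(meta, indent=1))

    gt = {
        "seed": study.seed,
        "radius": study.radius,
        "shape": list(study.layout.shape),
        "image_ids": study.cohort.image_ids,
        "affected_ids": study.cohort.affected_ids,
        "target_labels": study.target_labels,
        "landmarks": {k: list(v) for k, v in study.layout.landmarks.items()},
        "feature_regions": {k: [list(c), list(r)]
                            for k, (c, r) in study.layout.feature_regions.items()},
    }
    (d / "ground_truth.json").write_text(json.dumps(gt, indent=1, sort_keys=True))
    return d


@dataclass
class StudyBundle:
    """In-memory view of a study directory (or a ToyStudy)."""

    fixations: list[FixationEvent]
    responses: list[ResponseRecord]
    mask: FaceMask
    shape: tuple[int, int]
    image_ids: list[str]
    affected_ids: list[str]
    images: dict[str, np.ndarray]
    classifiers: list
    target_labels: dict[str, str]
    aois: list[AOIRegion]
    radius: int


def load_study(directory) -> StudyBundle:
    d = Path(directory)
    gt = json.loads((d / "ground_truth.json").read_text())
    mask = gio.read_mask_png(d / "mask.png")
    images = {}
    for row in gio.read_manifest(d / "images" / "manifest.csv").itertuples(index=False):
        images[str(row.image_id)] = gio.read_map_png(d / "images" / row.filename,
                                                     float(row.scale))
    classifiers = []
    croot = d / "classifiers"
    for cdir in sorted(croot.iterdir()) if croot.exists() else []:
        meta = json.loads((cdir / "meta.json").read_text())
        protos = {lab: gio.read_map_png(cdir / f"{lab}.png", meta["scales"][lab])
                  for lab in meta["labels"]}
        classifiers.append(PrototypeClassifier(meta["labels"], protos,
                                               temperature=meta["temperature"]))
    aois = gio.read_aois(d / "aois.json") if (d / "aois.json").exists() else []
    return StudyBundle(
        fixations=gio.read_fixations(d / "fixations.csv"),
        responses=gio.read_responses(d / "responses.csv"),
        mask=mask, shape=tuple(gt["shape"]), image_ids=list(gt["image_ids"]),
        affected_ids=list(gt["affected_ids"]), images=images,
        classifiers=classifiers, target_labels=dict(gt["target_labels"]),
        aois=aois, radius=int(gt["radius"]))


def bundle_from_toy(study: ToyStudy) -> StudyBundle:
    return StudyBundle(
        fixations=study.cohort.fixations, responses=study.cohort.responses,
        mask=study.mask, shape=study.layout.shape,
        image_ids=study.cohort.image_ids, affected_ids=study.cohort.affected_ids,
        images=study.images, classifiers=study.classifiers,
        target_labels=study.target_labels, aois=study.aois, radius=study.radius)


def simulate_to_dir(seed: int, directory, **kwargs) -> Path:
    """Generate the default synthetic study and write it as a bundle."""
    study = generate_toy_study(seed, **kwargs)
    return save_study(study, directory)


# -- orchestration ------------------------------------------------------------

def _fixations_by_trial(fixations) -> dict[tuple[str, str], list[FixationEvent]]:
    by: dict[tuple[str, str], list[FixationEvent]] = {}
    for f in fixations:
        by.setdefault((f.participant_id, f.image_id), []).append(f)
    return by


def replace_participant(m: AttentionMap, pid: str) -> AttentionMap:
    out = AttentionMap(m.grid, pid, m.group, m.image_id, m.stage)
    return out


def _cell_seed(base: int, *key: int) -> int:
    ss = np.random.SeedSequence(base, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2 ** 31))


class _StudyRun:
    """Holds the shared state of one run_study invocation."""

    def __init__(self, bundle: StudyBundle, params: StudyParams):
        self.b = bundle
        self.p = params
        self.groups_of = {pid: g for pid, g in
                          {r.participant_id: r.group for r in bundle.responses}.items()}
        self.trials = _fixations_by_trial(bundle.fixations)
        self.participants = sorted({pid for pid, _ in self.trials})
        self.correct = {(r.participant_id, r.image_id): r.correct
                        for r in bundle.responses}
        self.results: list[ComparisonResult] = []
        self.exclusions: list[dict] = []
        self.self_rows: list[dict] = []

    # rendering ---------------------------------------------------------------
    def _render(self, pid: str, image_id: str) -> np.ndarray:
        evs = self.trials.get((pid, image_id), [])
        m = render_from_fixations(evs, self.b.shape, radius=self.b.radius,
                                  group=self.groups_of.get(pid, "clinician"))
        return m.values

    def compute_common(self) -> dict[str, np.ndarray]:
        """Group common-attention maps: mean over every participant×image map."""
        sums = {g: np.zeros(self.b.shape) for g in GROUPS}
        counts = {g: 0 for g in GROUPS}
        for pid in self.participants:
            g = self.groups_of[pid]
            for image_id in self.b.image_ids:
                sums[g] += self._render(pid, image_id)
                counts[g] += 1
        return {g: sums[g] / max(counts[g], 1) for g in GROUPS}

    # subgroup machinery ------------------------------------------------------
    def subgroup(self, image_id: str, group: str, successful: bool) -> list[str]:
        return [pid for pid in self.participants
                if self.groups_of[pid] == group
                and (pid, image_id) in self.trials
                and self.correct.get((pid, image_id)) is successful]

    def member_maps(self, image_id: str, pids: Sequence[str], common: np.ndarray,
                    group: str) -> list[AttentionMap]:
        out = []
        for pid in pids:
            v = np.clip(self._render(pid, image_id) - common, 0.0, None)
            out.append(AttentionMap(IntensityGrid(v.astype(np.float32)),
                                    participant_id=pid, group=group,
                                    image_id=image_id, stage="common_subtracted"))
        return out

    def subgroup_average(self, members: Sequence[AttentionMap]) -> AttentionMap:
        avg = average_maps(list(members))
        return smooth(avg, self.p.smooth_kernel)

    def thresholded(self, avg: AttentionMap, level: str) -> AttentionMap:
        return apply_noise_threshold(avg, self.p.threshold(level),
                                     mask=self.b.mask, level=level)

    def prep_closure(self, level: str, population: Sequence[AttentionMap]):
        """Bootstrap preprocessing: average resampled members → threshold.

        Members are already common-subtracted; smoothing is omitted in the
        replicates (it barely moves coverage-ranked cutoffs but triples the
        per-replicate cost).  The population's maps are stacked once so a
        replicate average is a single weighted matrix product.
        """
        spec = self.p.threshold(level)
        mask = self.b.mask
        stack = np.stack([m.values for m in population]).reshape(len(population), -1)
        stack = np.ascontiguousarray(stack, dtype=np.float32)
        index_of = {id(m): i for i, m in enumerate(population)}

        def prep(members: Sequence[AttentionMap]):
            w = np.zeros(len(population), dtype=np.float32)
            for m in members:
                w[index_of[id(m)]] += 1.0
            w /= w.sum()
            acc = (w @ stack).astype(np.float64).reshape(self.b.shape)
            if spec.mode == "coverage_fraction":
                t = coverage_cutoff(acc, mask, spec.value)
            elif spec.mode == "fraction_of_max":
                t = spec.value * acc.max()
            else:
                t = spec.value
            return np.where(acc < t, 0.0, acc)

        return prep

    # bookkeeping -------------------------------------------------------------
    def exclude(self, pair: str, level: str, image_id: str, reason: str) -> None:
        self.exclusions.append({"pair": pair, "level": level,
                                "image_id": image_id, "reason": reason})

    def emit(self, image_id: str, pair: str, level: str, a: AttentionMap, other,
             side_a_members: Sequence[AttentionMap], cell_key: tuple[int, ...]) -> None:
        """Compare a subgroup map against ``other`` and record the result."""
        va = a.values
        vb = other.values if hasattr(other, "values") else np.asarray(other)
        i = iou(va, vb)
        if np.isnan(i):
            self.exclude(pair, level, image_id, "iou undefined (both maps empty)")
            return
        k = symmetric_kl(va, vb, eps=self.p.kl_eps, mask=self.b.mask)
        seed = _cell_seed(self.p.seed, *cell_key)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            iou_sd, kl_sd = bootstrap_sds_both(
                list(side_a_members), vb, ["iou", lambda x, y: symmetric_kl(
                    x, y, eps=self.p.kl_eps, mask=self.b.mask)],
                self.prep_closure(level, side_a_members),
                B=self.p.bootstrap_B, seed=seed)
        self.results.append(ComparisonResult(
            image_id=image_id, pair=pair, level=level, iou=float(i), kl=float(k),
            iou_sd=iou_sd, kl_sd=kl_sd,
            n_pixels_a=int(np.count_nonzero(va[self.b.mask.mask])),
            n_pixels_b=int(np.count_nonzero(vb[self.b.mask.mask]))))


def run_study(bundle: StudyBundle, params: StudyParams, out_dir,
              write_maps: bool = False) -> dict:
    """Run the complete analysis and write the report tables to ``out_dir``.

    Returns a summary dict (also written as ``run_meta.json``) with row
    and exclusion counts for the bookkeeping invariant: for every pair,
    rows emitted + cells excluded = images × levels of that pair's grid.
    With ``write_maps`` the common and subgroup-average maps (smoothed and
    at both threshold levels) are also written under ``out_dir/maps``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = params
    run = _StudyRun(bundle, p)
    common = run.compute_common()
    saved_maps: list[AttentionMap] = []
    if write_maps:
        for g in GROUPS:
            saved_maps.append(AttentionMap(IntensityGrid(common[g]), "GROUP_AVG",
                                           g, "COMMON", "raw"))

    # per-image subgroup averages at each level, kept for reuse
    levels_of_pair = {"clin_vs_saliency": ("low", "high"),
                      "clin_vs_nonclin": ("low", "high"),
                      "success_vs_under": ("low",)}
    pair_grid: dict[str, list[str]] = {}

    # self-consistency accumulators: per participant, affected / unaffected sums
    want_self = "self_consistency" in p.pairs
    self_acc: dict[str, dict[str, np.ndarray]] = {}
    self_n: dict[str, dict[str, int]] = {}

    saliency_cache: dict[str, SaliencyMap] = {}
    occ = p.occlusion()

    for ii, image_id in enumerate(bundle.image_ids):
        affected = image_id in bundle.affected_ids
        members: dict[tuple[str, bool], list[AttentionMap]] = {}
        averages: dict[tuple[str, bool], AttentionMap] = {}
        for g in GROUPS:
            for success in (True, False):
                pids = run.subgroup(image_id, g, success)
                if len(pids) >= p.min_subgroup:
                    ms = run.member_maps(image_id, pids, common[g], g)
                    members[(g, success)] = ms
                    averages[(g, success)] = run.subgroup_average(ms)
                    if write_maps:
                        tag = "success" if success else "under"
                        avg = averages[(g, success)]
                        saved_maps.append(replace_participant(avg, f"AVG_{tag}"))
                        for level in ("low", "high"):
                            saved_maps.append(replace_participant(
                                run.thresholded(avg, level), f"AVG_{tag}"))

        if want_self:
            for g in GROUPS:
                for success in (True, False):
                    for m in members.get((g, success), []):
                        pid = m.participant_id
                        side = "affected" if affected else "unaffected"
                        acc = self_acc.setdefault(pid, {})
                        n = self_n.setdefault(pid, {})
                        if side not in acc:
                            acc[side] = np.zeros(bundle.shape)
                            n[side] = 0
                        acc[side] += m.values
                        n[side] += 1

        # pair 1: successful clinicians vs coverage-matched ensemble saliency
        if "clin_vs_saliency" in p.pairs and affected:
            pair_grid.setdefault("clin_vs_saliency", []).append(image_id)
            sal = None
            if (g := ("clinician", True)) in averages:
                if image_id not in saliency_cache:
                    try:
                        parts = [saliency_at_resolution(
                            bundle.images[image_id], clf,
                            bundle.target_labels[image_id], occ,
                            out_shape=bundle.shape, image_id=image_id)
                            for clf in bundle.classifiers]
                        saliency_cache[image_id] = ensemble_saliency(parts)
                    except UnreliableSaliencyError as e:
                        saliency_cache[image_id] = None  # type: ignore[assignment]
                        run.exclude("clin_vs_saliency", "low", image_id, str(e))
                        run.exclude("clin_vs_saliency", "high", image_id, str(e))
                sal = saliency_cache[image_id]
                if sal is not None:
                    for li, level in enumerate(("low", "high")):
                        ref = run.thresholded(averages[g], level)
                        try:
                            matched = match_coverage(sal, ref, bundle.mask)
                        except ValueError as e:
                            run.exclude("clin_vs_saliency", level, image_id, str(e))
                            continue
                        run.emit(image_id, "clin_vs_saliency", level, ref,
                                 matched.grid, members[g], (1, li, ii))
            else:
                for level in ("low", "high"):
                    run.exclude("clin_vs_saliency", level, image_id,
                                f"successful-clinician subgroup below "
                                f"{p.min_subgroup} participants")

        # pair 2: successful clinicians vs successful non-clinicians
        if "clin_vs_nonclin" in p.pairs:
            pair_grid.setdefault("clin_vs_nonclin", []).append(image_id)
            a, bb = ("clinician", True), ("nonclinician", True)
            for li, level in enumerate(("low", "high")):
                if a in averages and bb in averages:
                    run.emit(image_id, "clin_vs_nonclin", level,
                             run.thresholded(averages[a], level),
                             run.thresholded(averages[bb], level).grid,
                             members[a], (2, li, ii))
                else:
                    missing = "clinician" if a not in averages else "non-clinician"
                    run.exclude("clin_vs_nonclin", level, image_id,
                                f"successful {missing} subgroup below "
                                f"{p.min_subgroup} participants")

        # pair 3: successful vs underperforming within each group, low level
        if "success_vs_under" in p.pairs:
            for gi, g in enumerate(GROUPS):
                pair = f"success_vs_under_{g}"
                pair_grid.setdefault(pair, []).append(image_id)
                a, bb = (g, True), (g, False)
                if a in averages and bb in averages:
                    run.emit(image_id, pair, "low",
                             run.thresholded(averages[a], "low"),
                             run.thresholded(averages[bb], "low").grid,
                             members[a], (3, gi, ii))
                else:
                    which = "successful" if a not in averages else "underperforming"
                    run.exclude(pair, "low", image_id,
                                f"{which} {g} subgroup below "
                                f"{p.min_subgroup} participants")

    # self-consistency: affected vs unaffected within participant, low level
    if want_self:
        spec = p.threshold("low")
        for pid in sorted(self_acc):
            acc, n = self_acc[pid], self_n[pid]
            if "affected" not in acc or "unaffected" not in acc:
                run.exclude("self_consistency", "low", pid,
                            "participant lacks maps on one image class")
                continue
            try:
                va = apply_noise_threshold(
                    AttentionMap(IntensityGrid(acc["affected"] / n["affected"]), pid,
                                 run.groups_of[pid], "AFFECTED_AVG", "common_subtracted"),
                    spec, mask=bundle.mask, level="low").values
                vb = apply_noise_threshold(
                    AttentionMap(IntensityGrid(acc["unaffected"] / n["unaffected"]), pid,
                                 run.groups_of[pid], "UNAFFECTED_AVG", "common_subtracted"),
                    spec, mask=bundle.mask, level="low").values
                i = iou(va, vb)
                if np.isnan(i):
                    raise ValueError("iou undefined (both maps empty)")
                k = symmetric_kl(va, vb, eps=p.kl_eps, mask=bundle.mask)
            except ValueError as e:
                run.exclude("self_consistency", "low", pid, str(e))
                continue
            run.self_rows.append({"participant_id": pid, "group": run.groups_of[pid],
                                  "iou": float(i), "kl": float(k),
                                  "n_affected_maps": n["affected"],
                                  "n_unaffected_maps": n["unaffected"]})

    # pooling -----------------------------------------------------------------
    df = pd.DataFrame([{c: getattr(r, c) for c in gio.COMPARISON_COLUMNS}
                       for r in run.results], columns=gio.COMPARISON_COLUMNS)
    pooled_rows = []
    for (pair, level), sub in df.groupby(["pair", "level"], sort=True):
        for metric in ("iou", "kl"):
            mr = random_effects_pool(sub[metric].to_numpy(),
                                     sub[f"{metric}_sd"].to_numpy() ** 2)
            pooled_rows.append({"pair": pair, "level": level, "metric": metric,
                                "pooled": mr.pooled, "se": mr.se,
                                "ci_lo": mr.ci95[0], "ci_hi": mr.ci95[1],
                                "tau2": mr.tau2, "k": mr.k})

    # response statistics -----------------------------------------------------
    per_image, overall = accuracy_table(bundle.responses)
    ov = overall.set_index("group")
    chi_rows = []
    if set(GROUPS) <= set(ov.index):
        a, b = int(ov.loc["clinician", "correct"]), int(ov.loc["clinician", "incorrect"])
        c, d = int(ov.loc["nonclinician", "correct"]), int(ov.loc["nonclinician", "incorrect"])
        try:
            stat, pval = chi_square_2x2(a, b, c, d)
        except ValueError:
            stat = pval = float("nan")  # degenerate margin (e.g. nobody wrong)
        chi_rows.append({"clin_correct": a, "clin_incorrect": b,
                         "nonclin_correct": c, "nonclin_incorrect": d,
                         "statistic": stat, "p_value": pval})

    # outputs -----------------------------------------------------------------
    if write_maps and saved_maps:
        gio.write_maps(out / "maps", saved_maps)
    gio.write_comparisons(out / "comparisons.csv", run.results)
    gio.write_meta_results(out / "pooled.csv", pooled_rows)
    pd.DataFrame(run.self_rows, columns=["participant_id", "group", "iou", "kl",
                                         "n_affected_maps", "n_unaffected_maps"]
                 ).to_csv(out / "self_consistency.csv", index=False)
    pd.DataFrame(run.exclusions, columns=["pair", "level", "image_id", "reason"]
                 ).to_csv(out / "exclusions.csv", index=False)
    per_image.to_csv(out / "accuracy_per_image.csv", index=False)
    overall.to_csv(out / "accuracy_overall.csv", index=False)
    pd.DataFrame(chi_rows).to_csv(out / "chi_square.csv", index=False)
    if bundle.aois:
        rows = [{"participant_id": m.participant_id, "image_id": m.image_id,
                 "aoi": m.aoi, "duration_of_fixation_ms": m.duration_of_fixation_ms,
                 "time_to_first_whole_fixation_ms":
                     "" if m.time_to_first_whole_fixation_ms is None
                     else m.time_to_first_whole_fixation_ms}
                for m in aoi_metrics(bundle.fixations, bundle.aois)]
        pd.DataFrame(rows).to_csv(out / "aoi_metrics.csv", index=False)

    # bookkeeping invariant: rows + exclusions = images × levels per pair
    expected = {}
    for pair, imgs in pair_grid.items():
        nlevels = len(levels_of_pair.get(
            "success_vs_under" if pair.startswith("success_vs_under") else pair, ("low",)))
        expected[pair] = len(imgs) * nlevels
    excl_df = pd.DataFrame(run.exclusions, columns=["pair", "level", "image_id", "reason"])
    summary = {
        "n_images": len(bundle.image_ids),
        "n_participants": len(run.participants),
        "rows_emitted": {pair: int((df["pair"] == pair).sum()) for pair in expected},
        "cells_excluded": {pair: int((excl_df["pair"] == pair).sum()) for pair in expected},
        "expected_cells": expected,
        "self_consistency_rows": len(run.self_rows),
        "params": {**asdict(p), "pairs": list(p.pairs)},
    }
    (out / "run_meta.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


def run_study_from_dir(cfg: StudyConfig) -> dict:
    """Load a study bundle from disk and run the full analysis."""
    bundle = load_study(cfg.study_dir)
    return run_study(bundle, cfg.params, cfg.out_dir)
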