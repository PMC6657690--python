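"""Cell-separation and area-reconstruction error analysis.

Two error types are quantified against manually delineated (or synthetic)
groundtruth:

* **Cluster separation.**  Reference clusters — groups of ``n > 1`` touching
  groundtruth cells enclosed by a continuous detected border — index
  separation difficulty.  For each reference cluster a contingency table
  counts true positives ``a`` (member cells matched one-to-one by detected
  fibres), false negatives ``d = n - a`` and false positives ``b``
  (detections spanning more than one member cell); the sensitivity is
  ``a / (a + d)``.  Pipelines are compared with a paired bootstrap over
  reference clusters.

* **Area reconstruction.**  The Dice similarity coefficient
  ``DSC = 2|X n Y| / (|X| + |Y|)`` between groundtruth and reconstructed
  cell, restricted to cells correctly separated by all compared methods;
  distribution-level deviation is measured by the Kullback-Leibler
  divergence between binned area histograms over a range of bin sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .classify import initial_clusters
from .config import RidgeConfig, ValidationError
from .ridge import otsu_binarize, ridge_likelihood

#: Histogram bin sizes (px^2) over which KL-divergence curves are reported.
KL_BIN_SIZES = (50, 100, 200, 500, 1_000, 2_000, 5_000, 10_000, 20_000)


@dataclass
class ReferenceCluster:
    """A group of touching groundtruth cells enclosed by detected border."""

    cluster_id: int
    member_cell_ids: frozenset
    mask: np.ndarray

    @property
    def n(self) -> int:
        return len(self.member_cell_ids)


@dataclass
class ContingencyTable:
    """Separation outcome for one reference cluster of size ``n``."""

    n: int
    a: int
    b: int = 0
    c: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("reference cluster size n must be >= 1")
        if not 0 <= self.a <= self.n:
            raise ValidationError(f"need 0 <= a <= n, got a={self.a}, n={self.n}")
        if self.b < 0:
            raise ValidationError("b must be >= 0")

    @property
    def d(self) -> int:
        return self.n - self.a


@dataclass
class MatchResult:
    """One-to-one greedy matching between detections and groundtruth cells."""

    pairs: list  # (detected_id, groundtruth_id, dice)
    unmatched_detections: list
    unmatched_groundtruth: list

    def matched_groundtruth(self) -> set:
        return {g for _, g, _ in self.pairs}

    def dice_by_groundtruth(self) -> dict:
        return {g: s for _, g, s in self.pairs}


@dataclass
class BootstrapResult:
    """Outcome of a paired bootstrap comparison of two mean statistics."""

    p_value: float
    iterations: int
    seed: int
    means: np.ndarray | None = None


def sensitivity(table: ContingencyTable) -> float:
    """Fraction of member cells correctly separated: a / (a + d)."""
    return table.a / (table.a + table.d)


def dice(x: np.ndarray, y: np.ndarray) -> float:
    """Dice similarity coefficient 2|X n Y| / (|X| + |Y|) of two masks."""
    xm = np.asarray(x).astype(bool)
    ym = np.asarray(y).astype(bool)
    nx, ny = int(xm.sum()), int(ym.sum())
    if nx + ny == 0:
        raise ValidationError("Dice undefined for two empty masks")
    return 2.0 * int((xm & ym).sum()) / (nx + ny)


def reference_clusters(image: np.ndarray, groundtruth: np.ndarray,
                       ridge_cfg: RidgeConfig | None = None
                       ) -> list[ReferenceCluster]:
    """Reference clusters from gradient analysis of the image.

    Border pixels are the Otsu-binarised ridge map dilated once (3x3);
    clusters are the border-encapsulated components.  Each groundtruth cell
    is assigned to the cluster holding the majority of its pixels; clusters
    with fewer than two assigned cells are dropped.
    """
    img = np.asarray(image)
    gt = np.asarray(groundtruth)
    if img.shape != gt.shape:
        raise ValidationError("image and groundtruth shapes differ")
    border = otsu_binarize(ridge_likelihood(img, ridge_cfg))
    border = ndi.binary_dilation(border, structure=np.ones((3, 3), dtype=bool))
    clusters = initial_clusters(border)
    members: dict[int, set] = {}
    for cell_id in np.unique(gt):
        if cell_id == 0:
            continue
        cell = gt == cell_id
        labels, counts = np.unique(clusters[cell], return_counts=True)
        majority = int(labels[np.argmax(counts)])
        if majority > 0:
            members.setdefault(majority, set()).add(int(cell_id))
    out = []
    for cid in sorted(members):
        if len(members[cid]) > 1:
            out.append(
                ReferenceCluster(
                    cluster_id=cid,
                    member_cell_ids=frozenset(members[cid]),
                    mask=clusters == cid,
                )
            )
    return out


def group_and_filter(clusters, min_samples: int = 5) -> dict:
    """Group reference clusters (or any sized samples) by n; drop small groups."""
    groups: dict[int, list] = {}
    for rc in clusters:
        groups.setdefault(rc.n, []).append(rc)
    return {n: g for n, g in sorted(groups.items()) if len(g) >= min_samples}


def match_detections(detected: np.ndarray, groundtruth: np.ndarray,
                     min_dice: float = 0.5) -> MatchResult:
    """Greedy one-to-one matching by descending pairwise Dice (>= min_dice)."""
    det = np.asarray(detected)
    gt = np.asarray(groundtruth)
    if det.shape != gt.shape:
        raise ValidationError("detected and groundtruth shapes differ")
    det_areas = _label_areas(det)
    gt_areas = _label_areas(gt)
    overlap = (det > 0) & (gt > 0)
    pair_codes, pair_counts = np.unique(
        det[overlap].astype(np.int64) * (gt.max() + 1) + gt[overlap],
        return_counts=True,
    )
    candidates = []
    for code, cnt in zip(pair_codes, pair_counts):
        d_id = int(code // (gt.max() + 1))
        g_id = int(code % (gt.max() + 1))
        score = 2.0 * cnt / (det_areas[d_id] + gt_areas[g_id])
        if score >= min_dice:
            candidates.append((score, d_id, g_id))
    # descending dice; ties resolved by ascending (detected, groundtruth) id
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_d: set[int] = set()
    used_g: set[int] = set()
    pairs = []
    for score, d_id, g_id in candidates:
        if d_id in used_d or g_id in used_g:
            continue
        pairs.append((d_id, g_id, float(score)))
        used_d.add(d_id)
        used_g.add(g_id)
    return MatchResult(
        pairs=pairs,
        unmatched_detections=sorted(set(det_areas) - used_d),
        unmatched_groundtruth=sorted(set(gt_areas) - used_g),
    )


def contingency(rc: ReferenceCluster, match: MatchResult,
                detected: np.ndarray, groundtruth: np.ndarray,
                min_overlap_fraction: float = 0.1) -> ContingencyTable:
    """Contingency table of one reference cluster against the detections.

    ``a`` counts member cells with an accepted one-to-one match; ``b`` counts
    detections inside the cluster region that span at least two member cells,
    each covering at least ``min_overlap_fraction`` of the detection's area.
    """
    det = np.asarray(detected)
    gt = np.asarray(groundtruth)
    matched = match.matched_groundtruth()
    a = sum(1 for cell in rc.member_cell_ids if cell in matched)
    region = rc.mask
    b = 0
    for d_id in np.unique(det[region]):
        if d_id == 0:
            continue
        det_mask = det == d_id
        det_area = int(det_mask.sum())
        covered = 0
        for cell in rc.member_cell_ids:
            frac = int((det_mask & (gt == cell)).sum()) / det_area
            if frac >= min_overlap_fraction:
                covered += 1
        if covered >= 2:
            b += 1
    return ContingencyTable(n=rc.n, a=a, b=b)


def bootstrap_compare(values_pl1, values_pl2, B: int = 100_000,
                      seed: int = 0, keep_means: bool = False
                      ) -> BootstrapResult:
    """Paired bootstrap test of H0: mean(pl2) >= mean(pl1).

    Each iteration resamples reference-cluster indices with replacement and
    evaluates both pipelines on the same resample; the p-value is the
    fraction of iterations in which H0 holds.
    """
    v1 = np.asarray(values_pl1, dtype=np.float64)
    v2 = np.asarray(values_pl2, dtype=np.float64)
    if v1.size == 0 or v1.shape != v2.shape:
        raise ValidationError("paired value sequences must be nonempty and equal length")
    rng = np.random.default_rng(seed)
    n = v1.size
    hits = 0
    means = [] if keep_means else None
    chunk = max(1, min(B, 20_000_000 // max(n, 1)))
    done = 0
    while done < B:
        b = min(chunk, B - done)
        idx = rng.integers(0, n, size=(b, n))
        m1 = v1[idx].mean(axis=1)
        m2 = v2[idx].mean(axis=1)
        hits += int(np.count_nonzero(m2 >= m1))
        if keep_means:
            means.append(np.stack([m1, m2], axis=1))
        done += b
    return BootstrapResult(
        p_value=hits / B,
        iterations=B,
        seed=seed,
        means=np.concatenate(means) if keep_means else None,
    )


def kl_area_divergence(areas_p, areas_q, bin_size: float) -> float:
    """KL divergence D(P||Q) between binned area distributions.

    Shared bins of width ``bin_size`` span [0, joint maximum]; counts are
    normalised to probabilities; P=0 terms contribute 0; empty Q bins are
    epsilon-smoothed (1e-12 added to every Q bin, then renormalised);
    natural logarithm.
    """
    p = np.asarray(areas_p, dtype=np.float64)
    q = np.asarray(areas_q, dtype=np.float64)
    if p.size == 0 or q.size == 0:
        raise ValidationError("area sequences must be nonempty")
    if bin_size <= 0:
        raise ValidationError("bin_size must be > 0")
    top = max(p.max(), q.max())
    edges = np.arange(0.0, top + 2 * bin_size, bin_size)
    hp, _ = np.histogram(p, bins=edges)
    hq, _ = np.histogram(q, bins=edges)
    pp = hp / hp.sum()
    qq = hq.astype(np.float64) + 1e-12
    qq /= qq.sum()
    nz = pp > 0
    return float(np.sum(pp[nz] * np.log(pp[nz] / qq[nz])))


def area_density(areas, bin_size: float = 800.0,
                 bandwidth_factor: float = 0.2,
                 n_grid: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density estimate of the binned area histogram.

    The histogram (bin width ``bin_size``) is smoothed with Gaussian kernels
    of bandwidth ``bandwidth_factor`` times the sample standard deviation;
    the returned (grid, density) curve integrates to 1 within 1e-3.
    """
    a = np.asarray(areas, dtype=np.float64)
    if a.size == 0:
        raise ValidationError("areas must be nonempty")
    sd = a.std(ddof=0)
    if sd == 0:
        raise ValidationError(
            "degenerate bandwidth: all areas identical, density undefined"
        )
    bw = bandwidth_factor * sd
    edges = np.arange(0.0, a.max() + 2 * bin_size, bin_size)
    counts, _ = np.histogram(a, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    weights = counts / counts.sum()
    lo = max(0.0, centers[0] - 5 * bw)
    hi = centers[-1] + 5 * bw
    grid = np.linspace(lo, hi, n_grid)
    diff = (grid[:, None] - centers[None, :]) / bw
    density = (weights[None, :] * np.exp(-0.5 * diff**2)).sum(axis=1)
    density /= bw * np.sqrt(2 * np.pi)
    # renormalise on the grid so the curve is a proper density even when
    # kernel mass near zero is clipped by the grid edge
    density /= np.trapezoid(density, grid)
    return grid, density


def evaluate_pipelines(images, groundtruths, pipeline_outputs: dict,
                       ridge_cfg: RidgeConfig | None = None,
                       B: int = 100_000, seed: int = 0,
                       min_samples: int = 5,
                       kl_bin_sizes=KL_BIN_SIZES) -> dict:
    """Joint separation / reconstruction report for several pipelines.

    ``pipeline_outputs`` maps method name -> list of fibre label images
    aligned with ``images`` and ``groundtruths``.  The report contains, per
    method, mean sensitivities by reference-cluster size, pairwise paired
    bootstrap p-values, Dice averages restricted to cells separated
    correctly by every compared method, and KL-divergence curves of the
    reconstructed-area distributions against the groundtruth areas.
    """
    methods = list(pipeline_outputs)
    records = []  # one per (image, reference cluster): sensitivities per method
    per_method_dice: dict[str, dict] = {m: {} for m in methods}
    matched_everywhere: list = []  # (img_idx, cell_id) matched by all methods
    gt_areas_all: list[float] = []
    rec_areas: dict[str, list] = {m: [] for m in methods}
    for idx, (img, gt) in enumerate(zip(images, groundtruths)):
        refs = reference_clusters(img, gt, ridge_cfg)
        matches = {m: match_detections(pipeline_outputs[m][idx], gt)
                   for m in methods}
        for rc in refs:
            sens = {}
            for m in methods:
                table = contingency(rc, matches[m], pipeline_outputs[m][idx], gt)
                sens[m] = sensitivity(table)
            records.append({"image": idx, "n": rc.n, "sensitivity": sens})
        # area restriction: cells matched one-to-one by every method
        gt_ids = set(np.unique(gt)) - {0}
        common = set.intersection(
            *(matches[m].matched_groundtruth() for m in methods)
        ) if methods else set()
        for cell in sorted(common & gt_ids):
            cell_mask = gt == cell
            gt_areas_all.append(float(cell_mask.sum()))
            for m in methods:
                det_id = next(
                    d for d, g, _ in matches[m].pairs if g == cell
                )
                det_mask = pipeline_outputs[m][idx] == det_id
                per_method_dice[m].setdefault("values", []).append(
                    dice(det_mask, cell_mask)
                )
                rec_areas[m].append(float(det_mask.sum()))
            matched_everywhere.append((idx, int(cell)))

    # group sensitivities by reference-cluster size
    by_size: dict[int, list] = {}
    for rec in records:
        by_size.setdefault(rec["n"], []).append(rec)
    by_size = {n: g for n, g in sorted(by_size.items()) if len(g) >= min_samples}

    sensitivity_report = {}
    for n, recs in by_size.items():
        entry = {"n_samples": len(recs)}
        for m in methods:
            vals = np.array([r["sensitivity"][m] for r in recs])
            entry[m] = {
                "mean": float(vals.mean()),
                "ci95": _bootstrap_ci(vals, seed=seed),
            }
        entry["p_values"] = {}
        for m1 in methods:
            for m2 in methods:
                if m1 == m2:
                    continue
                v1 = [r["sensitivity"][m1] for r in recs]
                v2 = [r["sensitivity"][m2] for r in recs]
                res = bootstrap_compare(v1, v2, B=B, seed=seed)
                entry["p_values"][f"{m1}>{m2}"] = res.p_value
        sensitivity_report[n] = entry

    overall = {}
    if records:
        overall["n_samples"] = len(records)
        for m1 in methods:
            for m2 in methods:
                if m1 == m2:
                    continue
                v1 = [r["sensitivity"][m1] for r in records]
                v2 = [r["sensitivity"][m2] for r in records]
                overall[f"p_{m1}>{m2}"] = bootstrap_compare(
                    v1, v2, B=B, seed=seed
                ).p_value
        for m in methods:
            overall[f"mean_{m}"] = float(
                np.mean([r["sensitivity"][m] for r in records])
            )

    dice_report = {}
    for m in methods:
        vals = per_method_dice[m].get("values", [])
        dice_report[m] = {
            "mean": float(np.mean(vals)) if vals else None,
            "n": len(vals),
        }
    if len(methods) >= 2 and matched_everywhere:
        dice_report["p_values"] = {}
        for m1 in methods:
            for m2 in methods:
                if m1 == m2:
                    continue
                res = bootstrap_compare(
                    per_method_dice[m1]["values"],
                    per_method_dice[m2]["values"],
                    B=B, seed=seed,
                )
                dice_report["p_values"][f"{m1}>{m2}"] = res.p_value

    kl_report = {}
    if gt_areas_all:
        for m in methods:
            if rec_areas[m]:
                kl_report[m] = {
                    int(h): kl_area_divergence(gt_areas_all, rec_areas[m], h)
                    for h in kl_bin_sizes
                }

    return {
        "methods": methods,
        "n_reference_clusters": len(records),
        "sensitivity_by_size": sensitivity_report,
        "overall": overall,
        "dice": dice_report,
        "kl_divergence": kl_report,
        "bootstrap": {"B": B, "seed": seed},
        "reference_cluster_sizes": sorted(
            np.unique([r["n"] for r in records]).tolist()
        ) if records else [],
    }


def _bootstrap_ci(values: np.ndarray, B: int = 2000, seed: int = 0,
                  level: float = 0.95) -> list:
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(B, values.size))
    means = values[idx].mean(axis=1)
    lo = (1 - level) / 2
    return [float(np.quantile(means, lo)), float(np.quantile(means, 1 - lo))]


def _label_areas(labels: np.ndarray) -> dict:
    ids, counts = np.unique(labels, return_counts=True)
    return {int(i): int(c) for i, c in zip(ids, counts) if i != 0}
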