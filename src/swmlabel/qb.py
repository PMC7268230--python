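"""Inter-subject labeling by online (QuickBundles-style) centroid clustering.

Within each region pair, the bundle centroids of all subjects are pooled and
clustered in a single pass: each centroid joins the existing cluster whose
running centroid is nearest in MDF, provided that distance does not exceed
the threshold; otherwise it seeds a new cluster.  The running centroid is
the incremental mean of flip-aligned members — clusters are never
recomputed, which is what makes the pass O(N^2) worst case and fast in
practice.

All bundles of an inter-subject cluster share one label.  When several
bundles of the *same* subject land in one cluster they are merged into a
single bundle (fiber union, centroid recomputed) — the behavioral contrast
with the matching method, which keeps such near-duplicates apart.

QuickBundles is order-dependent; for determinism bundles are processed in
subject-id order, then intra-subject label order.
"""

from __future__ import annotations

import numpy as np

from .geometry import mean_fiber
from .labeling import BundleLabel, LabeledBundle, LabeledBundleSet
from .matching import CohortLabels


def quickbundles(centroids: np.ndarray, threshold_mm: float) -> list:
    """Single-pass online clustering of resampled centroids.

    Returns a list of ``(member_indices, running_centroid)`` in creation
    order.  Members are flip-aligned to the running centroid before being
    averaged into it.
    """
    clusters: list = []   # [running_mean (21,3), n, members]
    for i, c in enumerate(np.asarray(centroids, dtype=float)):
        best, best_d, best_aligned = -1, np.inf, None
        for j, (mean, n, _) in enumerate(clusters):
            direct = np.linalg.norm(c - mean, axis=1).mean()
            flipped = np.linalg.norm(c[::-1] - mean, axis=1).mean()
            d, aligned = (direct, c) if direct <= flipped else (flipped, c[::-1])
            if d < best_d:
                best, best_d, best_aligned = j, d, aligned
        if best >= 0 and best_d <= threshold_mm:
            mean, n, members = clusters[best]
            clusters[best] = [(mean * n + best_aligned) / (n + 1), n + 1,
                              members + [i]]
        else:
            clusters.append([c.copy(), 1, [i]])
    return [(members, mean) for mean, _, members in clusters]


def qb_cohort(pair_map: dict, threshold_mm: float) -> CohortLabels:
    """Group-wise relabeling of a cohort with online centroid clustering."""
    rows = []
    new_sets: dict = {}

    for (hemi, pair) in sorted(pair_map):
        submap = pair_map[(hemi, pair)]
        pooled = [(subject, bundle)
                  for subject in sorted(submap)
                  for bundle in submap[subject]]
        cents = np.stack([b.centroid for _, b in pooled])
        clusters = quickbundles(cents, threshold_mm)
        a, b = pair.split("-")
        for new_index, (members, _) in enumerate(clusters):
            label = BundleLabel(hemi, a, b, new_index)
            per_subject: dict = {}
            for m in members:
                subject, bundle = pooled[m]
                per_subject.setdefault(subject, []).append(bundle)
            for subject, bundles in per_subject.items():
                if len(bundles) == 1:
                    merged = bundles[0]
                    fibers = merged.fibers
                    indices = merged.fiber_indices
                    centroid = merged.centroid
                else:
                    fibers = np.concatenate([bb.fibers for bb in bundles])
                    indices = np.concatenate([bb.fiber_indices for bb in bundles])
                    centroid = mean_fiber(fibers)
                nb = LabeledBundle(label, indices, fibers, centroid,
                                   bundles[0].point_init)
                new_sets.setdefault(subject, []).append(nb)
                rows.append({
                    "subject": subject, "hemisphere": hemi, "region_pair": pair,
                    "old_label": "+".join(bb.label.render() for bb in bundles),
                    "new_label": label.render(), "new_index": new_index,
                    "n_fibers": int(sum(bb.n_fibers for bb in bundles)),
                    "mdf_to_reference": np.nan,
                })

    bundle_sets = {s: LabeledBundleSet(s, sorted(bs, key=lambda x: x.label.render()))
                   for s, bs in new_sets.items()}
    return CohortLabels.from_rows("qb", threshold_mm, rows, bundle_sets)


#: Distance-threshold presets commonly explored, conservative to moderate (mm).
THRESHOLD_PRESETS = (10.0, 12.0, 18.0, 21.0)
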