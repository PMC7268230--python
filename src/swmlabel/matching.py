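"""Inter-subject labeling by threshold-gated minimum-cost matching.

Bundles are first grouped by the region pair they connect (the part of the
name that inter-subject relabeling never changes).  Within each region pair:

1. subjects are ordered by descending bundle count (ties by subject id);
2. the first subject is the reference; a rectangular minimum-cost assignment
   (Hungarian) between its bundle centroids and each following subject's is
   solved on the pairwise MDF matrix, and matched pairs whose MDF does not
   exceed the distance threshold inherit the reference bundle's index —
   pairs over the threshold stay unassigned;
3. reference bundles that match nobody keep their (fresh) index; unassigned
   bundles of other subjects wait;
4. the next subject in the order that still holds unassigned bundles becomes
   the reference, its unassigned bundles receive new indices from a single
   per-region-pair counter, and step 2 repeats — until no bundle is
   unassigned.

Each (subject, inter-subject label) holds exactly one bundle: near-duplicate
bundles within one subject keep separate labels (contrast with the
clustering method, which merges them).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .geometry import mdf_matrix
from .labeling import BundleLabel, LabeledBundle, LabeledBundleSet


def group_by_region_pair(subject_sets: dict) -> dict:
    """Map ``(hemisphere, region_pair) -> {subject_id: [LabeledBundle]}``.

    Every bundle of every subject appears under exactly one key; bundle lists
    are ordered by intra-subject position index.
    """
    out: dict = {}
    for subject_id in sorted(subject_sets):
        for bundle in subject_sets[subject_id].bundles:
            key = (bundle.label.hemisphere, bundle.label.region_pair)
            out.setdefault(key, {}).setdefault(subject_id, []).append(bundle)
    for submap in out.values():
        for bundles in submap.values():
            bundles.sort(key=lambda b: b.label.position_index)
    return out


def solve_assignment(M: np.ndarray):
    """Minimum-total-cost matching on a (possibly rectangular) cost matrix.

    Returns ``(rows, cols)`` index arrays of the ``min(n, m)`` matched pairs;
    surplus elements of the larger side are unmatched.
    """
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("cost matrix must be finite")
    return linear_sum_assignment(M)


@dataclass
class CohortLabels:
    """Result of a group-wise relabeling run.

    ``table`` has one row per (possibly merged) bundle: subject, hemisphere,
    region_pair, old_label(s), new_label, new_index, n_fibers and — for the
    matching method — the MDF to the reference bundle that named it.
    ``bundle_sets`` holds the relabeled per-subject bundle sets.
    """

    method: str
    threshold_mm: float
    table: pd.DataFrame
    bundle_sets: dict

    _COLUMNS = ["subject", "hemisphere", "region_pair", "old_label",
                "new_label", "new_index", "n_fibers", "mdf_to_reference"]

    @classmethod
    def from_rows(cls, method, threshold_mm, rows, bundle_sets):
        table = pd.DataFrame(rows, columns=cls._COLUMNS)
        table = table.sort_values(["subject", "new_label"]).reset_index(drop=True)
        return cls(method, threshold_mm, table, bundle_sets)


def match_cohort(pair_map: dict, threshold_mm: float) -> CohortLabels:
    """Run the iterative reference matching over a whole cohort."""
    rows = []
    new_sets: dict = {}

    def emit(subject, hemi, pair, bundle, new_index, mdf):
        a, b = pair.split("-")
        label = BundleLabel(hemi, a, b, new_index)
        nb = LabeledBundle(label, bundle.fiber_indices, bundle.fibers,
                           bundle.centroid, bundle.point_init)
        new_sets.setdefault(subject, []).append(nb)
        rows.append({
            "subject": subject, "hemisphere": hemi, "region_pair": pair,
            "old_label": bundle.label.render(), "new_label": label.render(),
            "new_index": new_index, "n_fibers": bundle.n_fibers,
            "mdf_to_reference": mdf,
        })

    for (hemi, pair) in sorted(pair_map):
        submap = pair_map[(hemi, pair)]
        subjects = sorted(submap, key=lambda s: (-len(submap[s]), s))
        state = {s: [{"bundle": b, "index": None, "mdf": np.nan}
                     for b in submap[s]] for s in subjects}
        counter = 0
        for ri, ref in enumerate(subjects):
            ref_open = [e for e in state[ref] if e["index"] is None]
            if not ref_open:
                continue
            for e in ref_open:
                e["index"], e["mdf"] = counter, 0.0
                counter += 1
            ref_cents = np.stack([e["bundle"].centroid for e in ref_open])
            for other in subjects[ri + 1:]:
                oth_open = [e for e in state[other] if e["index"] is None]
                if not oth_open:
                    continue
                M = mdf_matrix(ref_cents,
                               np.stack([e["bundle"].centroid for e in oth_open]))
                r_idx, c_idx = solve_assignment(M)
                for r, c in zip(r_idx, c_idx):
                    if M[r, c] <= threshold_mm:
                        oth_open[c]["index"] = ref_open[r]["index"]
                        oth_open[c]["mdf"] = float(M[r, c])
        for subject in subjects:
            for e in state[subject]:
                emit(subject, hemi, pair, e["bundle"], e["index"], e["mdf"])

    bundle_sets = {s: LabeledBundleSet(s, sorted(bs, key=lambda b: b.label.render()))
                   for s, bs in new_sets.items()}
    return CohortLabels.from_rows("match", threshold_mm, rows, bundle_sets)
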