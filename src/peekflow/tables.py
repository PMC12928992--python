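"""Published validation-study tables as machine-readable fixtures.

The multi-laboratory validation campaign published aggregate tables — the
water-displacement reference conductances of PEEK tubing by colour and
laboratory, the inter-laboratory overlap of those reference ranges, QC
rejection counts, and the colour-specific plausibility thresholds.  These are
packaged verbatim under ``peekflow/data`` and the checks below tie the
package's arithmetic (range intersection, pooled-count overlap, cross-colour
ratios, rejection rate) back to the printed numbers.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .reference import range_intersection

_DATA = resources.files("peekflow") / "data"


def load_reference_table() -> pd.DataFrame:
    """Per colour/lab reference conductance aggregates (n, mean, min, max, CV%)."""
    with resources.as_file(_DATA / "reference_conductance.csv") as p:
        return pd.read_csv(p)


def load_overlap_table() -> pd.DataFrame:
    """Published inter-laboratory overlap ranges and in-overlap counts."""
    with resources.as_file(_DATA / "interlab_overlap.csv") as p:
        return pd.read_csv(p)


def load_validation_counts() -> dict:
    """Published QC outcome: totals, per-lab counts, rejection causes."""
    return json.loads((_DATA / "validation_counts.json").read_text())


def load_color_thresholds() -> dict:
    """Colour/lab-specific upper conductance plausibility bounds."""
    return json.loads((_DATA / "color_thresholds.json").read_text())


def load_manifest() -> dict:
    return json.loads((_DATA / "manifest.json").read_text())


def reference_overlap_summary() -> pd.DataFrame:
    """Recompute inter-laboratory overlap per colour from the reference table.

    For each colour, intersects the two labs' [min, max] reference ranges and
    expresses the published in-overlap count as a percent of the pooled
    determinations.  Columns: color, overlap_min, overlap_max, intersect_n,
    n_pooled, overlap_pct.
    """
    ref = load_reference_table()
    counts = load_overlap_table().set_index("color")
    rows = []
    for color, grp in ref.groupby("color", sort=False):
        by_lab = grp.set_index("lab")
        inter = range_intersection(
            (by_lab.loc["DRF", "min"], by_lab.loc["DRF", "max"]),
            (by_lab.loc["UQAM", "min"], by_lab.loc["UQAM", "max"]),
        )
        n_pooled = int(grp["n"].sum())
        n_in = int(counts.loc[color, "intersect_n"])
        rows.append({
            "color": color,
            "overlap_min": None if inter is None else inter[0],
            "overlap_max": None if inter is None else inter[1],
            "intersect_n": n_in,
            "n_pooled": n_pooled,
            "overlap_pct": 100.0 * n_in / n_pooled,
        })
    return pd.DataFrame(rows)


def cross_color_ratios() -> pd.DataFrame:
    """Mean-conductance ratios orange/blue and blue/yellow per laboratory."""
    ref = load_reference_table().set_index(["color", "lab"])["mean"]
    rows = []
    for lab in ("DRF", "UQAM"):
        rows.append({
            "lab": lab,
            "orange_over_blue": ref[("orange", lab)] / ref[("blue", lab)],
            "blue_over_yellow": ref[("blue", lab)] / ref[("yellow", lab)],
        })
    return pd.DataFrame(rows)


def published_rejection_rate_pct() -> float:
    """Overall QC rejection rate implied by the published counts, percent."""
    counts = load_validation_counts()
    return 100.0 * counts["rejected"] / counts["total"]
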