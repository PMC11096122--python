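import numpy as np
import pandas as pd
import pytest

from mitodlp.simulate import SimulationConfig, simulate_dataset


def make_variant_cells(position, ref, alt, fwd_alt, fwd_total, rev_alt, rev_total):
    """Rows for one variant across cells, from parallel per-cell count lists."""
    n = len(fwd_alt)
    return pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "position": position,
            "ref": ref,
            "alt": alt,
            "fwd_alt": fwd_alt,
            "rev_alt": rev_alt,
            "fwd_total": fwd_total,
            "rev_total": rev_total,
        }
    )


@pytest.fixture(scope="session")
def toy_filter_table():
    """Hand-constructed 12-variant table exercising every filter rule.

    Expected PASS set: positions 100, 400, 512, 526.
    """
    good = dict(fwd_alt=[2, 4, 6, 8], fwd_total=[10] * 4, rev_alt=[2, 4, 6, 8], rev_total=[10] * 4)
    parts = [
        # strand-support boundary: pooled 2+2, identical strand vectors (r=1)
        make_variant_cells(100, "A", "G", [1, 1, 0, 0], [10] * 4, [1, 1, 0, 0], [10] * 4),
        # one strand below 2 alternate reads
        make_variant_cells(101, "C", "T", [3, 0, 0, 0], [10] * 4, [1, 0, 0, 0], [10] * 4),
        # strand-exclusive evidence: also zero forward variance
        make_variant_cells(102, "G", "A", [0, 0, 0, 0], [10] * 4, [4, 3, 2, 1], [10] * 4),
        # perfect anticorrelation between strands (r = -1)
        make_variant_cells(200, "T", "C", [1, 5, 9], [10] * 3, [9, 5, 1], [10] * 3),
        # moderate anticorrelation (r = -0.4), below the R >= 0.2 rule
        make_variant_cells(300, "A", "T", [1, 2, 3, 4], [10] * 4, [4, 1, 3, 2], [10] * 4),
        # concordant strands, r = 0.18/sqrt(0.2*0.17) ~ 0.976
        make_variant_cells(400, "C", "G", [4, 8, 12, 16], [20] * 4, [5, 7, 13, 15], [20] * 4),
        make_variant_cells(512, "G", "C", **good),   # just before the first blacklist region
        make_variant_cells(513, "A", "G", **good),   # blacklist start (inclusive)
        make_variant_cells(525, "C", "A", **good),   # blacklist end (inclusive)
        make_variant_cells(526, "T", "G", **good),   # just after the first region
        make_variant_cells(3105, "G", "T", **good),  # second region start
        make_variant_cells(3109, "A", "C", **good),  # second region end
    ]
    return pd.concat(parts, ignore_index=True)


TOY_EXPECTED_PASS = {100, 400, 512, 526}


@pytest.fixture(scope="session")
def two_clone_dataset():
    """Canonical two-clone dataset with WGD used across stage tests."""
    cfg = SimulationConfig(
        n_libraries=2,
        cells_per_library=100,
        n_clones=2,
        wgd_fraction=0.3,
        n_variants=8,
        seed=0,
    )
    return simulate_dataset(cfg)


def clone_counts_matrices(counts):
    """Cell x variant alt/total matrices from the long count table."""
    alt = (
        counts.assign(a=counts["fwd_alt"] + counts["rev_alt"])
        .pivot_table(index="cell_id", columns="position", values="a", aggfunc="sum", fill_value=0)
    )
    tot = (
        counts.assign(t=counts["fwd_total"] + counts["rev_total"])
        .pivot_table(index="cell_id", columns="position", values="t", aggfunc="sum", fill_value=0)
    )
    return alt, tot


def align_clone_matrix(P_hat, labels_hat, labels_true, n_clones):
    """Reorder fitted clone rows to true clone indices by majority vote."""
    order = []
    for k in range(P_hat.shape[0]):
        members = labels_true[labels_hat == k]
        order.append(int(np.bincount(members, minlength=n_clones).argmax()) if len(members) else k)
    return np.asarray(order)
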