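"""Shared independent reference implementations used by the test suite."""

import numpy as np

from gweiskit.design import DesignMatrix


def design_from_matrix(matrix):
    matrix = np.asarray(matrix, dtype=float)
    return DesignMatrix(
        matrix,
        {"all": np.arange(matrix.shape[1])},
        np.arange(matrix.shape[0]),
        [f"x{i}" for i in range(matrix.shape[1])],
    )


def clump_reference(summary, r2, threshold, window_bp):
    """Literal restatement of the clumping rule, independent of the
    implementation: repeatedly take the smallest-p remaining SNP (ties by
    chromosome, position, id), discard remaining same-chromosome SNPs
    within the window whose r² reaches the threshold."""
    df = summary.reset_index(drop=True)
    order = df.sort_values(["P_ROBUST", "CHR", "BP", "SNP"], kind="mergesort").index.tolist()
    kept = []
    removed = set()
    for idx in order:
        if idx in removed:
            continue
        kept.append(idx)
        for j in order:
            if j == idx or j in removed or j in kept:
                continue
            if (
                df.loc[j, "CHR"] == df.loc[idx, "CHR"]
                and abs(int(df.loc[j, "BP"]) - int(df.loc[idx, "BP"])) <= window_bp
                and r2[idx, j] >= threshold
            ):
                removed.add(j)
    return [df.loc[i, "SNP"] for i in kept]
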