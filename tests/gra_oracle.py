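"""Independent literal recomputation of the grey relational pipeline.

Deliberately spreadsheet-style: nested Python loops over plain lists,
no numpy, no shared code with the package — so it can serve as an
oracle for the vectorized implementation.
"""


def gra_oracle(values, reference=1.0, rho=0.5, mode="per_sequence", weights=None):
    """values: list of rows (compounds) of equal length (receptors).

    Returns (diffs, coeffs, degrees) as plain lists.
    """
    n_rows = len(values)
    n_cols = len(values[0])
    diffs = [[abs(reference - values[k][i]) for i in range(n_cols)]
             for k in range(n_rows)]

    col_min = [min(diffs[k][i] for k in range(n_rows)) for i in range(n_cols)]
    col_max = [max(diffs[k][i] for k in range(n_rows)) for i in range(n_cols)]
    g_min = min(col_min)
    g_max = max(col_max)

    coeffs = []
    for k in range(n_rows):
        row = []
        for i in range(n_cols):
            if mode == "global":
                d_min, d_max = g_min, g_max
            else:
                d_min, d_max = col_min[i], col_max[i]
            row.append((d_min + rho * d_max) / (diffs[k][i] + rho * d_max))
        coeffs.append(row)

    if weights is None:
        weights = [1.0 / n_cols] * n_cols
    degrees = [sum(w * c for w, c in zip(weights, coeffs[k]))
               for k in range(n_rows)]
    return diffs, coeffs, degrees
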