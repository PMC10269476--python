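"""Brute-force overlap oracle: plain-Python feature walk, independent of
the vectorised implementation."""


def brute_force_overlap(matrix, mode):
    matrix = [list(map(float, row)) for row in matrix]
    n = len(matrix)
    n_features = len(matrix[0])
    levels = {k: 0.0 for k in range(1, n + 1)}
    if mode == "occurrence":
        denom = sum(1 for row in matrix for c in row if c > 0)
    else:
        denom = sum(c for row in matrix for c in row)
    for j in range(n_features):
        prevalence = sum(1 for i in range(n) if matrix[i][j] > 0)
        if prevalence == 0:
            continue
        if mode == "occurrence":
            levels[prevalence] += prevalence
        else:
            levels[prevalence] += sum(matrix[i][j] for i in range(n))
    return {k: 100.0 * v / denom for k, v in levels.items()}
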