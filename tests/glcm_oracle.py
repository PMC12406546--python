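"""Independent brute-force GLCM feature oracle.

Every feature is computed with literal Python loops over the matrix cells,
straight from the textbook definitions, with no shared code with the
package implementation.  Logs are base 2; 0*log(0) = 0; levels are 1..N_g.
"""

import math


def oracle_features(p):
    """All 20 features of a normalized, possibly asymmetric, GLCM ``p``
    (a list of lists or 2D array indexable as p[i][j], 0-based storage)."""
    ng = len(p)

    def log2(x):
        return math.log(x, 2)

    px = [0.0] * ng
    py = [0.0] * ng
    for i in range(ng):
        for j in range(ng):
            px[i] += p[i][j]
            py[j] += p[i][j]

    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    sigma_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng)))
    sigma_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng)))

    p_sum = [0.0] * (2 * ng + 1)  # index k = i+j, valid 2..2*ng
    p_diff = [0.0] * ng  # index k = |i-j|
    for i in range(ng):
        for j in range(ng):
            p_sum[(i + 1) + (j + 1)] += p[i][j]
            p_diff[abs(i - j)] += p[i][j]

    hx = -sum(v * log2(v) for v in px if v > 0)
    hy = -sum(v * log2(v) for v in py if v > 0)
    hxy = 0.0
    hxy1 = 0.0
    hxy2 = 0.0
    for i in range(ng):
        for j in range(ng):
            if p[i][j] > 0:
                hxy -= p[i][j] * log2(p[i][j])
            prod = px[i] * py[j]
            if prod > 0:
                if p[i][j] > 0:
                    hxy1 -= p[i][j] * log2(prod)
                hxy2 -= prod * log2(prod)

    asm = 0.0
    contrast = 0.0
    idm = 0.0
    sum_sq = 0.0
    autocorr = 0.0
    max_p = 0.0
    cp = 0.0
    cs = 0.0
    inn = 0.0
    idn = 0.0
    dissim = 0.0
    for i in range(ng):
        for j in range(ng):
            v = p[i][j]
            d = (i + 1) - (j + 1)
            asm += v * v
            contrast += d * d * v
            idm += v / (1.0 + d * d)
            sum_sq += ((i + 1) - mu_x) ** 2 * v
            autocorr += (i + 1) * (j + 1) * v
            max_p = max(max_p, v)
            c = (i + 1) + (j + 1) - mu_x - mu_y
            cp += c**4 * v
            cs += c**3 * v
            inn += v / (1.0 + abs(d) / ng)
            idn += v / (1.0 + d * d / (ng * ng))
            dissim += abs(d) * v

    if sigma_x * sigma_y > 0:
        correlation = (autocorr - mu_x * mu_y) / (sigma_x * sigma_y)
    else:
        correlation = 1.0

    sum_average = sum(k * p_sum[k] for k in range(2, 2 * ng + 1))
    sum_variance = sum((k - sum_average) ** 2 * p_sum[k] for k in range(2, 2 * ng + 1))
    sum_entropy = -sum(v * log2(v) for v in p_sum if v > 0)
    mu_d = sum(k * p_diff[k] for k in range(ng))
    diff_variance = sum((k - mu_d) ** 2 * p_diff[k] for k in range(ng))
    diff_entropy = -sum(v * log2(v) for v in p_diff if v > 0)

    hmax = max(hx, hy)
    imci = (hxy - hxy1) / hmax if hmax > 0 else 0.0
    imcii = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))

    return {
        "angular_second_moment": asm,
        "contrast": contrast,
        "correlation": correlation,
        "sum_of_squares_variance": sum_sq,
        "inverse_difference_moment": idm,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "entropy": hxy,
        "difference_variance": diff_variance,
        "difference_entropy": diff_entropy,
        "imci": imci,
        "imcii": imcii,
        "autocorrelation": autocorr,
        "maximum_probability": max_p,
        "cluster_prominence": cp,
        "cluster_shade": cs,
        "inn": inn,
        "idn": idn,
        "dissimilarity": dissim,
    }


def random_glcm(ng, rng):
    """A random normalized symmetric GLCM with a sparse support pattern."""
    m = rng.random((ng, ng)) * (rng.random((ng, ng)) < 0.6)
    m = m + m.T
    total = m.sum()
    if total == 0:
        m[0, 0] = 1.0
        total = 1.0
    return m / total
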