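"""Straight-line, loop-based reimplementation of the descriptor pipeline.

Used only by tests as an independent oracle: it shares no code with the
package and uses explicit Python loops instead of vectorized routines.
Intended for small images (<= ~64x64).
"""

import math


def gray(r, g, b, w=(0.299, 0.587, 0.114)):
    rows, cols = len(r), len(r[0])
    return [
        [w[0] * r[i][j] + w[1] * g[i][j] + w[2] * b[i][j] for j in range(cols)]
        for i in range(rows)
    ]


def minmax(img):
    lo = min(min(row) for row in img)
    hi = max(max(row) for row in img)
    return [[(v - lo) / (hi - lo) for v in row] for row in img]


def box_smooth(img, window=3, border="replicate"):
    """Direct convolution with an all-equal unit-sum kernel."""
    rows, cols = len(img), len(img[0])
    half = window // 2
    coeff = 1.0 / (window * window)

    def px(i, j):
        if border == "replicate":
            i = min(max(i, 0), rows - 1)
            j = min(max(j, 0), cols - 1)
        else:  # reflect (symmetric, edge pixel repeated)
            if i < 0:
                i = -i - 1
            if i >= rows:
                i = 2 * rows - i - 1
            if j < 0:
                j = -j - 1
            if j >= cols:
                j = 2 * cols - j - 1
        return img[i][j]

    out = [[0.0] * cols for _ in range(rows)]
    for i in range(rows):
        for j in range(cols):
            s = 0.0
            for di in range(-half, half + 1):
                for dj in range(-half, half + 1):
                    s += px(i + di, j + dj)
            out[i][j] = s * coeff
    return out


def d1_row(img, i, j):
    cols = len(img[0])
    if j == 0:
        return img[i][1] - img[i][0]
    if j == cols - 1:
        return img[i][cols - 1] - img[i][cols - 2]
    return (img[i][j + 1] - img[i][j - 1]) / 2.0


def d1_col(img, i, j):
    rows = len(img)
    if i == 0:
        return img[1][j] - img[0][j]
    if i == rows - 1:
        return img[rows - 1][j] - img[rows - 2][j]
    return (img[i + 1][j] - img[i - 1][j]) / 2.0


def d2_row(img, i, j):
    cols = len(img[0])
    jj = min(max(j, 1), cols - 2)  # border rows take the nearest interior stencil
    return img[i][jj + 1] - 2.0 * img[i][jj] + img[i][jj - 1]


def d2_col(img, i, j):
    rows = len(img)
    ii = min(max(i, 1), rows - 2)
    return img[ii + 1][j] - 2.0 * img[ii][j] + img[ii - 1][j]


def first_mag(img):
    rows, cols = len(img), len(img[0])
    return [
        [math.hypot(d1_row(img, i, j), d1_col(img, i, j)) for j in range(cols)]
        for i in range(rows)
    ]


def second_mag(img):
    rows, cols = len(img), len(img[0])
    return [
        [math.hypot(d2_row(img, i, j), d2_col(img, i, j)) for j in range(cols)]
        for i in range(rows)
    ]


def crop(field, n):
    if n == 0:
        return field
    return [row[n:-n] for row in field[n:-n]]


def pop_std(field):
    vals = [v for row in field for v in row]
    n = len(vals)
    mean = sum(vals) / n
    return math.sqrt(sum((v - mean) ** 2 for v in vals) / n)


def descriptor_triple(img, smooth_window=3, border="replicate", crop_border=0,
                      normalize=True, do_smooth=True):
    """(activity, mobility, complexity) of one image given as nested lists."""
    if normalize:
        img = minmax(img)
    if do_smooth and smooth_window > 1:
        img = box_smooth(img, smooth_window, border)
    d1 = first_mag(img)
    d2 = second_mag(img)
    s_i = pop_std(crop(img, crop_border))
    s_1 = pop_std(crop(d1, crop_border))
    s_2 = pop_std(crop(d2, crop_border))
    act = s_i**2
    mob = s_1 / s_i
    cpx = (s_2 / s_1) / (s_1 / s_i)
    return act, mob, cpx
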