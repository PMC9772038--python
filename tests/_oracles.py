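"""Independent test oracles, kept separate from the implementation paths."""

import numpy as np


def brute_force_fit(x):
    """Closed-form least-squares trigonometric coefficients, term by term.

    Direct O(n^2) evaluation of a0 = mean, a_i = (2/n)*sum(x*cos(i*2*pi*t/n)),
    b_i = (2/n)*sum(x*sin(i*2*pi*t/n)) for i = 1..n//2, with the Nyquist
    cosine term (even n) at weight 1/n and its sine partner zero.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    t = np.arange(n)
    m = n // 2
    a0 = x.mean()
    a = np.empty(m)
    b = np.empty(m)
    for i in range(1, m + 1):
        ang = 2 * np.pi * i * t / n
        a[i - 1] = (2.0 / n) * np.sum(x * np.cos(ang))
        b[i - 1] = (2.0 / n) * np.sum(x * np.sin(ang))
    if n % 2 == 0:
        a[-1] /= 2.0
        b[-1] = 0.0
    return a0, a, b
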