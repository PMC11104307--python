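"""Naive reference learners used as an independent oracle in tests.

Each function below is a direct scalar-loop transcription of one
algorithm's per-step pseudocode, written without numpy and without
importing anything from the package under test.  They take a ready-made
sequence of feature activation vectors (lists of 0/1) and US values and
return the per-step predictions and weight histories.  Keeping them slow
and literal is the point: they share no code path with the vectorized
implementation they are checked against.
"""

import math


def _predict(w, f, rectify):
    s = 0.0
    for i in range(len(w)):
        s += f[i] * w[i]
    return max(s, 0.0) if rectify else s


def run_basic(f_seq, y_seq, lam, rectify=True):
    k = len(f_seq[0])
    w = [0.0] * k
    y_hats, w_hist = [], []
    for f, y in zip(f_seq, y_seq):
        y_hat = _predict(w, f, rectify)
        for i in range(k):
            w[i] = w[i] + lam * f[i] * (y - y_hat)
        y_hats.append(y_hat)
        w_hist.append(list(w))
    return {"y_hat": y_hats, "w": w_hist}


def run_decay(f_seq, y_seq, lam, rho, rectify=True):
    k = len(f_seq[0])
    w = [0.0] * k
    y_hats, w_hist = [], []
    for f, y in zip(f_seq, y_seq):
        y_hat = _predict(w, f, rectify)
        for i in range(k):
            decay = rho * w[i] if w[i] < 0 else 0.0
            w[i] = w[i] + lam * f[i] * (y - y_hat) - decay
        y_hats.append(y_hat)
        w_hist.append(list(w))
    return {"y_hat": y_hats, "w": w_hist}


def run_familiarity(f_seq, y_seq, lam_min, p, rectify=True):
    k = len(f_seq[0])
    w = [0.0] * k
    n = [0] * k
    y_hats, w_hist, n_hist = [], [], []
    for f, y in zip(f_seq, y_seq):
        y_hat = _predict(w, f, rectify)
        for i in range(k):
            n[i] = n[i] + f[i]  # count first ...
            lam_i = lam_min + 0.5 * (n[i] + 1) ** (-p)  # ... then rate
            w[i] = w[i] + lam_i * f[i] * (y - y_hat)
        y_hats.append(y_hat)
        w_hist.append(list(w))
        n_hist.append(list(n))
    return {"y_hat": y_hats, "w": w_hist, "n": n_hist}


def run_compact(f_seq, y_seq, lam_min, p, rho, mu, m, rectify=True, eta_floor=1e-4):
    k = len(f_seq[0])
    w = [0.0] * k
    n = [0] * k
    eta = [1.0] * k
    y_hats, w_hist, eta_hist = [], [], []
    for f, y in zip(f_seq, y_seq):
        present = any(f)
        if present:
            g = [eta[i] * f[i] for i in range(k)]
            g_norm = sum(abs(gi) ** m for gi in g) ** (1.0 / m)
            a = [gi / g_norm for gi in g]
            s = sum(a[i] * f[i] * w[i] for i in range(k))
            y_hat = max(s, 0.0) if rectify else s
        else:
            a = [0.0] * k
            y_hat = 0.0
        # per-feature loop in pseudocode order; eta update precedes the
        # weight update and both read the pre-update prediction
        old_w = list(w)
        for i in range(k):
            n[i] = n[i] + f[i]
            lam_i = lam_min + 0.5 * (n[i] + 1) ** (-p)
            if present:
                eta[i] = eta[i] + mu * f[i] * (1.0 / g_norm) * (y - y_hat) * (
                    old_w[i] * f[i] - a[i] ** (m - 1) * y_hat
                )
                eta[i] = max(eta[i], eta_floor)
            decay = rho * w[i] if w[i] < 0 else 0.0
            w[i] = w[i] + lam_i * a[i] * f[i] * (y - y_hat) - decay
        y_hats.append(y_hat)
        w_hist.append(list(w))
        eta_hist.append(list(eta))
    return {"y_hat": y_hats, "w": w_hist, "eta": eta_hist}


def run_variant(variant, f_seq, y_seq, params):
    """Dispatch on variant name using a fearsim ModelParams-like object."""
    if variant in ("basic", "configural"):
        return run_basic(f_seq, y_seq, params.lam, params.rectify)
    if variant == "decay":
        return run_decay(f_seq, y_seq, params.lam, params.rho, params.rectify)
    if variant == "familiarity":
        return run_familiarity(f_seq, y_seq, params.lam_min, params.p, params.rectify)
    if variant == "compact":
        return run_compact(
            f_seq,
            y_seq,
            params.lam_min,
            params.p,
            params.rho,
            params.mu,
            params.m,
            params.rectify,
            params.eta_floor,
        )
    raise ValueError(variant)
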