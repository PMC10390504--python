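"""Independent naive daily-loop implementations of all fourteen models.

These oracles are deliberately written as explicit per-day Python loops over
a single window — no vectorization, no shared code with the package's batch
implementations — so that exact agreement between the two code paths is a
meaningful check.  Conventions mirrored: the start day itself accumulates,
thresholds are met on the first day the running sum is >= the threshold,
integer day parameters are rounded, trigger/gate scans for senescence begin
at day 172, and emergence indices convert to calendar DOY as index - 122.
"""

import math

NOT_REACHED = None


def _sig(x):
    if x < -500:
        return 1.0 / (1.0 + math.exp(500.0))
    if x > 500:
        return 1.0 / (1.0 + math.exp(-500.0))
    return 1.0 / (1.0 + math.exp(-x))


def _day(x):
    return max(1, min(365, round(x)))


def _em_doy(idx):
    return None if idx is None else idx - 122


# ---------------------------------------------------------------- emergence

def tt(T, L, p):
    total = 0.0
    for d in range(_day(p["t0"]), 366):
        total += max(T[d - 1] - p["T_base"], 0.0)
        if total >= p["F_star"]:
            return _em_doy(d)
    return NOT_REACHED


def tts(T, L, p):
    total = 0.0
    for d in range(_day(p["t0"]), 366):
        total += _sig(p["b"] * (T[d - 1] - p["c"]))
        if total >= p["F_star"]:
            return _em_doy(d)
    return NOT_REACHED


def ptt(T, L, p):
    total = 0.0
    for d in range(_day(p["t0"]), 366):
        total += (L[d - 1] / 24.0) * max(T[d - 1] - p["T_base"], 0.0)
        if total >= p["F_star"]:
            return _em_doy(d)
    return NOT_REACHED


def ptts(T, L, p):
    total = 0.0
    for d in range(_day(p["t0"]), 366):
        total += (L[d - 1] / 24.0) * _sig(p["b"] * (T[d - 1] - p["c"]))
        if total >= p["F_star"]:
            return _em_doy(d)
    return NOT_REACHED


def m1(T, L, p):
    total = 0.0
    for d in range(_day(p["t0"]), 366):
        total += (L[d - 1] / 24.0) ** p["k"] * max(T[d - 1] - p["T_base"], 0.0)
        if total >= p["F_star"]:
            return _em_doy(d)
    return NOT_REACHED


def at(T, L, p):
    chill = 0
    force = 0.0
    for d in range(_day(p["t0"]), 366):
        if T[d - 1] < p["T_c"]:
            chill += 1
        force += max(T[d - 1] - p["T_c"], 0.0)
        arg = p["c"] * chill
        arg = max(-500.0, min(500.0, arg))
        if force >= p["a"] + p["b"] * math.exp(arg):
            return _em_doy(d)
    return NOT_REACHED


def sq(T, L, p):
    if not p["T_min"] < p["T_opt"] < p["T_max"]:
        return NOT_REACHED
    chill = 0.0
    done = None
    for d in range(_day(p["t0_chill"]), 366):
        t = T[d - 1]
        if t <= p["T_min"] or t >= p["T_max"]:
            rate = 0.0
        elif t <= p["T_opt"]:
            rate = (t - p["T_min"]) / (p["T_opt"] - p["T_min"])
        else:
            rate = (p["T_max"] - t) / (p["T_max"] - p["T_opt"])
        chill += rate
        if chill >= p["C_star"]:
            done = d
            break
    if done is None:
        return NOT_REACHED
    force = 0.0
    for d in range(done, 366):
        force += max(T[d - 1] - p["T_base"], 0.0)
        if force >= p["F_star"]:
            return _em_doy(d)
    return NOT_REACHED


def dp(T, L, p):
    induction = 0.0
    ind_day = None
    for d in range(_day(p["t0_di"]), 366):
        f_T = _sig(-p["a_di"] * (T[d - 1] - p["b_di"]))
        f_L = _sig(-10.0 * (L[d - 1] - p["c_di"]))
        induction += f_T * f_L
        if induction >= p["D_star"]:
            ind_day = d
            break
    if ind_day is None:
        return NOT_REACHED
    C = 0.0
    F = 0.0
    for d in range(ind_day, 366):
        C += _sig(-p["a_ch"] * (T[d - 1] - p["c_ch"]))
        F += _sig(p["b_f"] * (T[d - 1] - p["c_f"])) * _sig(p["g_L"] * (L[d - 1] - p["h_L"]))
        arg = max(-500.0, min(500.0, -p["F_b"] * C))
        if F >= p["F_a"] * math.exp(arg):
            return _em_doy(d)
    return NOT_REACHED


# --------------------------------------------------------------- senescence

SOLSTICE = 172


def wm(T, L, p):
    for d in range(SOLSTICE, 366):
        if (T[d - 1] < p["T_crit"] and L[d - 1] < p["L_crit"]) or T[d - 1] < p["T_frost"]:
            return d
    return NOT_REACHED


def dm_rates(T, L, p):
    x = max(0, min(2, round(p["x"])))
    y = max(0, min(2, round(p["y"])))
    rates = []
    for t, l in zip(T, L):
        if t < p["T_b"] and l < p["L_b"]:
            rates.append((p["T_b"] - t) ** x * (l / p["L_b"]) ** y)
        else:
            rates.append(0.0)
    return rates


def dm(T, L, p, threshold=None):
    thr = p["Y_star"] if threshold is None else threshold
    rates = dm_rates(T, L, p)
    total = 0.0
    for d in range(_day(p["start"]), 366):
        total += rates[d - 1]
        if total >= thr:
            return d
    return NOT_REACHED


def jm(T, L, p):
    gate = None
    for d in range(SOLSTICE, 366):
        if L[d - 1] < p["P_crit"]:
            gate = d
            break
    if gate is None:
        return NOT_REACHED
    total = 0.0
    for d in range(gate, 366):
        total += max(p["T_b"] - T[d - 1], 0.0)
        if total >= p["Y_star"]:
            return d
    return NOT_REACHED


def dpdi_rates(T, L, p):
    return [
        _sig(-p["a"] * (t - p["b"])) * _sig(-10.0 * (l - p["c"]))
        for t, l in zip(T, L)
    ]


def dpdi(T, L, p, threshold=None):
    thr = p["D_star"] if threshold is None else threshold
    rates = dpdi_rates(T, L, p)
    total = 0.0
    for d in range(_day(p["start"]), 366):
        total += rates[d - 1]
        if total >= thr:
            return d
    return NOT_REACHED


def _adjusted_threshold(base, sos_cur, sos_ref, alpha):
    return max(base * (1.0 + alpha * (sos_cur - sos_ref)), 1e-6)


def dms(T, L, p, T_em, L_em, T_clim, L_clim, sos_params):
    sos_cur = ptts(T_em, L_em, sos_params)
    sos_ref = ptts(T_clim, L_clim, sos_params)
    if sos_cur is None or sos_ref is None:
        return NOT_REACHED
    thr = _adjusted_threshold(p["Y_star"], sos_cur + 122, sos_ref + 122, p["alpha"])
    return dm(T, L, p, threshold=thr)


def dpdis(T, L, p, T_em, L_em, T_clim, L_clim, sos_params):
    sos_cur = ptts(T_em, L_em, sos_params)
    sos_ref = ptts(T_clim, L_clim, sos_params)
    if sos_cur is None or sos_ref is None:
        return NOT_REACHED
    thr = _adjusted_threshold(p["D_star"], sos_cur + 122, sos_ref + 122, p["alpha"])
    return dpdi(T, L, p, threshold=thr)


EMERGENCE_ORACLES = {
    "TT": tt, "TTs": tts, "PTT": ptt, "PTTs": ptts, "M1": m1,
    "AT": at, "SQ": sq, "DP": dp,
}
SENESCENCE_ORACLES = {"WM": wm, "DM": dm, "JM": jm, "DPDI": dpdi}
SOS_ADJUSTED_ORACLES = {"DMs": dms, "DPDIs": dpdis}
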