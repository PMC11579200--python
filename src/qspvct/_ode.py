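"""Low-level ODE right-hand side and integrator for the reduced QSP-IO model.

Everything in this module is numba-compiled and operates on flat float64
arrays; the public, named API lives in :mod:`qspvct.model_core`.  The state
and parameter layouts are frozen here as integer constants and mirrored by
name in ``model_core`` — keep the two in sync.

The integrator is an adaptive Dormand–Prince 5(4) pair that steps exactly
onto a caller-supplied output grid (dosing discontinuities are handled by
the caller, which integrates segment by segment and applies bolus jumps).
The dynamics are deliberately parameterized so that no rate exceeds a few
per day, which keeps the explicit pair efficient; masking and receptor
binding are treated as fast equilibria (see model_core docs).
"""

import numpy as np
from numba import njit

# ---------------------------------------------------------------- state layout
I_C = 0       # cancer cells, tumor (count)
I_TE_T = 1    # CD8 effector T cells, tumor
I_TH_T = 2    # CD4 helper T cells, tumor
I_TR_T = 3    # regulatory T cells, tumor
I_AP_T = 4    # mature APC, tumor
I_M1 = 5      # M1 macrophages, tumor
I_M2 = 6      # M2 macrophages, tumor
I_CY = 7      # cytokine pool, tumor (arbitrary units)
I_AP_L = 8    # mature APC, TDLN
I_TE_L = 9    # activated CD8, TDLN
I_TH_L = 10   # activated CD4, TDLN
I_TR_L = 11   # activated Treg, TDLN
I_TE_C = 12   # circulating CD8, central
I_TH_C = 13   # circulating CD4, central
I_TR_C = 14   # circulating Treg, central
I_AI_C = 15   # intact (uncleaved) antibody, central (mol)
I_ACL_C = 16  # cleaved antibody, central (mol)
I_AI_P = 17   # intact antibody, peripheral
I_ACL_P = 18  # cleaved antibody, peripheral
I_AI_L = 19   # intact antibody, TDLN
I_ACL_L = 20  # cleaved antibody, TDLN
I_AI_T = 21   # intact antibody, tumor
I_ACL_T = 22  # cleaved antibody, tumor
I_CLV = 23    # cumulative cleaved antibody (mol, bookkeeping)

N_STATE = 24

# ------------------------------------------------------------- parameter layout
P_GROWTH = 0          # tumor growth rate (1/day)
P_INIT_DIAM = 1       # pre-treatment tumor diameter (cm); used by the VP stages
P_KD_NEO = 2          # neoantigen binding constant Kd (M)
P_TCC = 3             # tumor-specific T cell clones (count)
P_K_CLEAVE = 4        # mask-linker cleavage rate in the tumor (1/day)
P_MASK_KM = 5         # masking equilibrium constant (dimensionless)
P_K_EXH = 6           # T cell exhaustion rate by cancer cells (1/day)
P_K_KILL = 7          # CD8 killing rate constant (1/day per effector)
P_K_CLEAR = 8         # antibody clearance from central (1/day)
P_BODY_MASS = 9       # body mass (kg)
P_CELL_VOL = 10       # cancer cell volume (mL)
P_PACKING = 11        # tumor packing fraction (dimensionless)
P_C_MAX = 12          # logistic carrying capacity (cells)
P_K_C_HALF = 13       # half-saturation cancer count for immune contact
P_KD_AB = 14          # antibody / PD-L1 Kd (M)
P_MW_AB = 15          # antibody molecular weight (g/mol)
P_PDL1_PER_CELL = 16  # out-of-synapse PD-L1 copies per cancer cell
P_S_HALF = 17         # synapse PD-1 engagement half-saturation (relative)
P_ETA_KILL = 18       # max fractional kill inhibition by PD-1 engagement
P_EXH_BASE = 19       # checkpoint-independent fraction of exhaustion
P_V_CENTRAL = 20      # central volume (mL)
P_V_PERIPH = 21       # peripheral volume (mL)
P_V_TDLN = 22         # TDLN volume (mL)
P_Q_PERIPH = 23       # central<->peripheral exchange flow (mL/day)
P_Q_TDLN = 24         # central<->TDLN exchange flow (mL/day)
P_K_PERM = 25         # tumor vascular exchange rate (1/day, per tumor mL)
P_KD_REF_NEO = 26     # reference neoantigen Kd for presentation strength (M)
P_K_TCC_HALF = 27     # TCC half-saturation for priming
P_APC_POOL = 28       # immature APC pool available in the tumor
P_K_APC_MAT = 29      # APC maturation rate (1/day)
P_K_APC_MIG = 30      # APC migration rate tumor->TDLN (1/day)
P_D_APC_T = 31        # mature APC death, tumor (1/day)
P_D_APC_L = 32        # mature APC death, TDLN (1/day)
P_K_PRIME_CD8 = 33    # CD8 priming rate (cells/APC/day)
P_K_PRIME_CD4 = 34    # CD4 priming rate (cells/APC/day)
P_K_PRIME_TREG = 35   # Treg priming rate (cells/APC/day)
P_K_EGRESS = 36       # T cell egress TDLN->central (1/day)
P_D_T_L = 37          # T cell death, TDLN (1/day)
P_D_T_C = 38          # T cell death, central (1/day)
P_D_T_T = 39          # T cell death, tumor (1/day)
P_K_INFIL = 40        # T cell infiltration central->tumor (1/day)
P_V_HALF = 41         # tumor volume half-saturation for recruitment (mL)
P_K_TREG_HALF = 42    # Treg suppression half-saturation (cells)
P_K_M2_HALF = 43      # M2 suppression half-saturation (cells)
P_MAC_POOL = 44       # monocyte/macrophage precursor pool
P_K_M1_REC = 45       # M1 recruitment rate (1/day)
P_K_M2_REC = 46       # M2 recruitment rate (1/day)
P_K_MAC_POL = 47      # M1 -> M2 polarization rate (1/day)
P_D_MAC = 48          # macrophage death (1/day)
P_K_CYT_KILL = 49     # cytokine release per killed cancer cell (au/cell)
P_K_CYT_TUM = 50      # tumor-driven cytokine production (au/day)
P_D_CYT = 51          # cytokine decay (1/day)
P_K_CYT_HALF = 52     # cytokine half-saturation (au)
P_SIGMA_P = 53        # peripheral vascular partition (0..1, antibody)

N_PARAM = 54

_V_T_FLOOR = 1e-9  # mL; keeps antibody concentrations finite for tiny tumors


@njit(cache=True)
def tumor_volume_ml(cells, cell_vol, packing):
    return cells * cell_vol / packing


@njit(cache=True)
def rhs(t, y, p, fopen, dy):
    """Time derivative of the full state. ``fopen`` is the equilibrium
    binding-competent fraction of intact antibody (1.0 for the unmasked arm)."""
    c = y[I_C]
    v_t = tumor_volume_ml(c, p[P_CELL_VOL], p[P_PACKING])
    if v_t < _V_T_FLOOR:
        v_t = _V_T_FLOOR

    # --- checkpoint pharmacology (quasi-static receptor occupancy) ---------
    # binding-competent antibody concentration in tumor interstitium (M)
    a_act = 1000.0 * (fopen * y[I_AI_T] + y[I_ACL_T]) / v_t
    occ = a_act / (a_act + p[P_KD_AB])        # PD-L1 occupancy by antibody
    l_un = 1.0 - occ                          # unblocked synapse PD-L1 (rel.)
    s = l_un / (l_un + p[P_S_HALF])           # PD-1 engagement

    f_c = c / (c + p[P_K_C_HALF])             # immune contact saturation
    supp = 1.0 / (1.0 + y[I_TR_T] / p[P_K_TREG_HALF])
    supp = supp / (1.0 + y[I_M2] / p[P_K_M2_HALF])
    kill = p[P_K_KILL] * y[I_TE_T] * f_c * (1.0 - p[P_ETA_KILL] * s) * supp

    # --- tumor ------------------------------------------------------------
    dy[I_C] = p[P_GROWTH] * c * (1.0 - c / p[P_C_MAX]) - kill

    # --- cytokine and APCs --------------------------------------------------
    cyf = y[I_CY] / (y[I_CY] + p[P_K_CYT_HALF])
    dy[I_CY] = (p[P_K_CYT_KILL] * kill + p[P_K_CYT_TUM] * f_c
                - p[P_D_CYT] * y[I_CY])
    dy[I_AP_T] = (p[P_K_APC_MAT] * cyf * p[P_APC_POOL]
                  - (p[P_K_APC_MIG] + p[P_D_APC_T]) * y[I_AP_T])
    dy[I_AP_L] = p[P_K_APC_MIG] * y[I_AP_T] - p[P_D_APC_L] * y[I_AP_L]

    # --- priming in the TDLN ------------------------------------------------
    psi = p[P_TCC] / (p[P_TCC] + p[P_K_TCC_HALF])       # clonal breadth
    phi = p[P_KD_REF_NEO] / (p[P_KD_REF_NEO] + p[P_KD_NEO])  # presentation
    k_out = p[P_K_EGRESS] + p[P_D_T_L]
    dy[I_TE_L] = p[P_K_PRIME_CD8] * psi * phi * y[I_AP_L] - k_out * y[I_TE_L]
    dy[I_TH_L] = p[P_K_PRIME_CD4] * psi * phi * y[I_AP_L] - k_out * y[I_TH_L]
    dy[I_TR_L] = p[P_K_PRIME_TREG] * y[I_AP_L] - k_out * y[I_TR_L]

    # --- trafficking --------------------------------------------------------
    w = v_t / (v_t + p[P_V_HALF])
    k_in = p[P_K_INFIL] * w
    dy[I_TE_C] = p[P_K_EGRESS] * y[I_TE_L] - (p[P_D_T_C] + k_in) * y[I_TE_C]
    dy[I_TH_C] = p[P_K_EGRESS] * y[I_TH_L] - (p[P_D_T_C] + k_in) * y[I_TH_C]
    dy[I_TR_C] = p[P_K_EGRESS] * y[I_TR_L] - (p[P_D_T_C] + k_in) * y[I_TR_C]

    exh = p[P_K_EXH] * f_c * (p[P_EXH_BASE] + (1.0 - p[P_EXH_BASE]) * s)
    dy[I_TE_T] = k_in * y[I_TE_C] - (p[P_D_T_T] + exh) * y[I_TE_T]
    dy[I_TH_T] = k_in * y[I_TH_C] - p[P_D_T_T] * y[I_TH_T]
    dy[I_TR_T] = k_in * y[I_TR_C] - p[P_D_T_T] * y[I_TR_T]

    # --- macrophages --------------------------------------------------------
    pol = p[P_K_MAC_POL] * f_c
    dy[I_M1] = (p[P_K_M1_REC] * cyf * p[P_MAC_POOL]
                - (p[P_D_MAC] + pol) * y[I_M1])
    dy[I_M2] = (p[P_K_M2_REC] * f_c * p[P_MAC_POOL] + pol * y[I_M1]
                - p[P_D_MAC] * y[I_M2])

    # --- antibody PK (amounts, mol) ----------------------------------------
    vc = p[P_V_CENTRAL]
    vp = p[P_V_PERIPH]
    vl = p[P_V_TDLN]
    sig = p[P_SIGMA_P]
    jp_i = p[P_Q_PERIPH] * (sig * y[I_AI_C] / vc - y[I_AI_P] / vp)
    jp_c = p[P_Q_PERIPH] * (sig * y[I_ACL_C] / vc - y[I_ACL_P] / vp)
    jl_i = p[P_Q_TDLN] * (y[I_AI_C] / vc - y[I_AI_L] / vl)
    jl_c = p[P_Q_TDLN] * (y[I_ACL_C] / vc - y[I_ACL_L] / vl)
    qt = p[P_K_PERM] * v_t
    jt_i = qt * (y[I_AI_C] / vc - y[I_AI_T] / v_t)
    jt_c = qt * (y[I_ACL_C] / vc - y[I_ACL_T] / v_t)

    clv = p[P_K_CLEAVE] * y[I_AI_T]  # proteolysis happens in the TME only

    dy[I_AI_C] = -p[P_K_CLEAR] * y[I_AI_C] - jp_i - jl_i - jt_i
    dy[I_ACL_C] = -p[P_K_CLEAR] * y[I_ACL_C] - jp_c - jl_c - jt_c
    dy[I_AI_P] = jp_i
    dy[I_ACL_P] = jp_c
    dy[I_AI_L] = jl_i
    dy[I_ACL_L] = jl_c
    dy[I_AI_T] = jt_i - clv
    dy[I_ACL_T] = jt_c + clv
    dy[I_CLV] = clv


# ------------------------------------------------- Dormand–Prince 5(4) stepper

@njit(cache=True)
def _dp_step(t, y, h, p, fopen, k1, y5, y4):
    """One Dormand-Prince step. k1 must hold rhs(t, y). Fills y5 (5th order)
    and y4 (embedded 4th order); returns nothing."""
    n = y.shape[0]
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    k5 = np.empty(n)
    k6 = np.empty(n)
    k7 = np.empty(n)
    yt = np.empty(n)

    for i in range(n):
        yt[i] = y[i] + h * (1.0 / 5.0) * k1[i]
    rhs(t + h / 5.0, yt, p, fopen, k2)
    for i in range(n):
        yt[i] = y[i] + h * (3.0 / 40.0 * k1[i] + 9.0 / 40.0 * k2[i])
    rhs(t + 3.0 * h / 10.0, yt, p, fopen, k3)
    for i in range(n):
        yt[i] = y[i] + h * (44.0 / 45.0 * k1[i] - 56.0 / 15.0 * k2[i]
                            + 32.0 / 9.0 * k3[i])
    rhs(t + 4.0 * h / 5.0, yt, p, fopen, k4)
    for i in range(n):
        yt[i] = y[i] + h * (19372.0 / 6561.0 * k1[i] - 25360.0 / 2187.0 * k2[i]
                            + 64448.0 / 6561.0 * k3[i] - 212.0 / 729.0 * k4[i])
    rhs(t + 8.0 * h / 9.0, yt, p, fopen, k5)
    for i in range(n):
        yt[i] = y[i] + h * (9017.0 / 3168.0 * k1[i] - 355.0 / 33.0 * k2[i]
                            + 46732.0 / 5247.0 * k3[i] + 49.0 / 176.0 * k4[i]
                            - 5103.0 / 18656.0 * k5[i])
    rhs(t + h, yt, p, fopen, k6)
    for i in range(n):
        y5[i] = y[i] + h * (35.0 / 384.0 * k1[i] + 500.0 / 1113.0 * k3[i]
                            + 125.0 / 192.0 * k4[i] - 2187.0 / 6784.0 * k5[i]
                            + 11.0 / 84.0 * k6[i])
    rhs(t + h, y5, p, fopen, k7)
    for i in range(n):
        y4[i] = y[i] + h * (5179.0 / 57600.0 * k1[i] + 7571.0 / 16695.0 * k3[i]
                            + 393.0 / 640.0 * k4[i] - 92097.0 / 339200.0 * k5[i]
                            + 187.0 / 2100.0 * k6[i] + 1.0 / 40.0 * k7[i])


@njit(cache=True)
def integrate_grid(y0, t_grid, p, fopen, rtol, atol, max_step, stop_above_c,
                   out):
    """Integrate from t_grid[0], writing the state at every grid time into
    ``out`` (shape len(t_grid) x N_STATE).  Steps land exactly on grid times.

    If ``stop_above_c`` > 0, integration stops at the first *grid* time where
    the cancer-cell count is >= stop_above_c.  Returns the number of grid rows
    filled (== len(t_grid) when no early stop).  Negative state entries are
    clipped to zero after each accepted step (solver-tolerance undershoot)."""
    n = y0.shape[0]
    y = y0.copy()
    out[0, :] = y
    if stop_above_c > 0.0 and y[I_C] >= stop_above_c:
        return 1

    k1 = np.empty(n)
    y5 = np.empty(n)
    y4 = np.empty(n)
    h = min(max_step, 0.1)
    t = t_grid[0]
    for m in range(1, t_grid.shape[0]):
        t_target = t_grid[m]
        while t < t_target - 1e-12 * max(1.0, abs(t_target)):
            if h > max_step:
                h = max_step
            if t + h > t_target:
                h = t_target - t
            rhs(t, y, p, fopen, k1)
            accepted = False
            while not accepted:
                _dp_step(t, y, h, p, fopen, k1, y5, y4)
                # weighted RMS error norm
                err = 0.0
                bad = False
                for i in range(n):
                    if not np.isfinite(y5[i]):
                        bad = True
                        break
                    sc = atol[i] + rtol * max(abs(y[i]), abs(y5[i]))
                    e = (y5[i] - y4[i]) / sc
                    err += e * e
                if bad:
                    h *= 0.25
                    if h < 1e-12:
                        return -m  # signal failure at grid row m
                    continue
                err = np.sqrt(err / n)
                if err <= 1.0:
                    t = t + h
                    for i in range(n):
                        y[i] = y5[i] if y5[i] > 0.0 else 0.0
                    accepted = True
                    fac = 5.0 if err == 0.0 else min(5.0, 0.9 * err ** -0.2)
                    h = h * max(0.2, fac)
                else:
                    h = h * max(0.2, 0.9 * err ** -0.2)
                    if h < 1e-12:
                        return -m
        out[m, :] = y
        if stop_above_c > 0.0 and y[I_C] >= stop_above_c:
            return m + 1
    return t_grid.shape[0]
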