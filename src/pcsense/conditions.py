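"""Reference study conditions for the synthetic two-genotype experiment.

These constants define the ground truth the generators reproduce: wild-type
(WT) baseline values, the knock-out (KO) effect sizes (mean differences,
KO - WT) imposed on the generators, the reported 95% confidence intervals
those effects were measured with, and the group sizes. Downstream recovery
analyses (pipeline summaries, acceptance checks) measure how well the
analysis chain re-estimates these imposed effects.

Baselines marked "free" are not constrained by the reference study and were
chosen once as physiologically typical Purkinje-cell values.
"""

# --- spontaneous firing (units: neurons; N = 14 WT, 15 KO) -----------------
N_NEURONS_WT = 14
N_NEURONS_KO = 15

WT_SS_RATE_HZ = 60.0          # free baseline (typical PC simple-spike rate)
SS_RATE_MD_HZ = 3.68          # KO - WT, not significant

WT_CS_RATE_HZ = 1.0           # free baseline (typical PC complex-spike rate)
CS_RATE_MD_HZ = -0.259
CS_RATE_MD_CI = (-0.426, -0.0951)

WT_SS_CV = 0.5                # free baseline
SS_CV_MD = 0.138
SS_CV_MD_CI = (0.0422, 0.266)

RECORDING_DURATION_S = 100.0  # minimum inclusion duration

# --- intrinsic excitability (units: cells; N = 11 WT, 13 KO) ---------------
N_CELLS_WT = 11
N_CELLS_KO = 13

WT_RHEOBASE_PA = 600.0        # free baseline (PC from hyperpolarized holding)
RHEOBASE_MD_PA = -205.0
RHEOBASE_MD_CI = (-382.0, -36.4)
# between-cell SD inferred from the reported CI of the mean difference:
# SD ~= (CI halfwidth) / (1.96 * sqrt(1/n_wt + 1/n_ko))
RHEOBASE_SD_PA = 215.0

# --- morphometry (units: cells; N = 14 WT, 15 KO) ---------------------------
N_TREES_WT = 14
N_TREES_KO = 15

WT_APICAL_UM = 180.0          # free baseline (PC soma-to-apical-tip length)
APICAL_MD_UM = -61.89
APICAL_MD_CI = (-89.6, -35.7)
APICAL_SD_UM = 37.0           # inferred from the CI as above

SPINE_DENSITY_PER_UM = 2.3    # free baseline
SPINE_DENSITY_MD = 0.246      # KO - WT, not significant


def ko_cs_rate_hz() -> float:
    return WT_CS_RATE_HZ + CS_RATE_MD_HZ


def ko_ss_rate_hz() -> float:
    return WT_SS_RATE_HZ + SS_RATE_MD_HZ


def ko_ss_cv() -> float:
    return WT_SS_CV + SS_CV_MD


def ko_rheobase_pa() -> float:
    return WT_RHEOBASE_PA + RHEOBASE_MD_PA


def ko_apical_um() -> float:
    return WT_APICAL_UM + APICAL_MD_UM
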