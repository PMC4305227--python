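"""Bundled worked-example reference data.

Small curated tables from the published PBMC expression study of COPD
and its acute exacerbation that this pipeline re-implements: per-gene
fold changes for the two biomarker panels, the two-step trajectory fold
pairs, the signed stable-relative trajectories, the per-patient DESS
totals and the clinical lung-function values.  They serve as worked
examples whose expected outputs are known, so the selection, scoring and
classification operations can be exercised end to end without any
download.

Row identity is the array sequence id (several rows can share one gene
symbol); fold values are ratios >= 1 with the direction given by the
subtable they were printed in.
"""

from __future__ import annotations

import io

import pandas as pd

from .design import AECOPD_COMPARISONS, COPD_COMPARISONS
from .diffexp import DOWN, UP

# --- COPD-specific panel example -------------------------------------------
# Four comparisons: STABLE, AE1, AE3, AE10 -- each vs CON.
# 14 rows co-upregulated and 23 rows co-downregulated at >= 5-fold.

_COPD_UP = """\
seq_id\tsymbol\tSTABLE_vs_CON\tAE1_vs_CON\tAE3_vs_CON\tAE10_vs_CON
D12502\tCEACAM1\t10.1\t83.0\t66.5\t10.5
NM_004369\tCOL6A3\t10.4\t21.0\t22.4\t10.8
AF064599\tNOL3\t12.1\t13.6\t16.3\t11.5
BC042586\tCOL1A2\t13.1\t72.3\t92.9\t17.2
BC014473\tCEACAM1\t14.7\t101.2\t61.0\t11.8
AY358857\tMLPH\t17.0\t10.3\t12.8\t12.2
AF348143\tMUC1\t20.0\t19.7\t20.1\t28.6
NM_012385\tP8\t20.1\t19.1\t21.3\t22.1
BC093946\tUNQ473\t20.2\t45.9\t53.1\t24.3
NM_001305\tCLDN4\t23.0\t34.4\t39.1\t20.7
NM_002933\tRNASE1\t26.9\t12.5\t15.2\t37.2
BC053636\tH19\t29.5\t37.2\t28.0\t11.8
BC069423\tDEFA1\t33.0\t96.1\t86.7\t10.2
XM_928349\tLOC653600\t43.1\t115.8\t109.4\t12.8
"""

_COPD_DOWN = """\
seq_id\tsymbol\tSTABLE_vs_CON\tAE1_vs_CON\tAE3_vs_CON\tAE10_vs_CON
M38056\tHLA-DOA\t5.3\t5.9\t5.6\t7.3
AY209188\tSAA3P\t5.3\t6.7\t6.4\t11.9
BC069511\tUBASH3A\t5.5\t10.4\t14.3\t6.9
AJ421515\tCRTAC1\t5.6\t25.4\t12.5\t11.9
AL133666\tEPHA6\t5.6\t5.8\t8.2\t5.3
NM_020152\tC21orf7\t5.7\t8.2\t9.7\t10.4
XM_089384\tTTC24\t5.8\t11.7\t12.5\t12.7
NM_006850\tIL24\t6.0\t6.5\t10.7\t11.1
AL713701\tC21orf7\t6.1\t9.5\t9.5\t10.0
XM_931594\tLOC643514\t6.2\t11.4\t5.7\t7.4
NM_006159\tNELL2\t6.3\t11.5\t7.3\t10.0
NM_002348\tLY9\t6.7\t8.2\t7.4\t6.5
XM_934852\tLOC129293\t6.9\t14.5\t12.9\t9.4
BC062589\tLY9\t6.9\t7.3\t7.1\t5.5
XM_934149\tKIAA0748\t7.0\t7.5\t11.2\t6.2
BC008567\tC21orf7\t7.3\t6.3\t7.5\t7.7
NM_138363\tCCDC45\t7.8\t6.4\t5.9\t5.2
BC022101\tUNQ470\t7.8\t44.1\t18.1\t32.3
BC027920\tLY9\t7.9\t6.2\t5.8\t5.3
BC033896\tAK5\t8.2\t8.2\t10.6\t9.9
XM_085151\tYLPM1\t10.7\t8.7\t5.1\t7.4
NM_014553\tTFCP2L1\t16.1\t21.8\t32.0\t14.9
NM_001007098\tSCP2\t21.0\t27.9\t18.7\t18.6
"""

# --- AECOPD-specific panel example -----------------------------------------
# Six comparisons: AE1, AE3, AE10 -- each vs CON and vs STABLE.
# 8 rows co-upregulated >= 10-fold and 8 rows co-downregulated >= 3-fold.

_AECOPD_UP = """\
seq_id\tsymbol\tAE1_vs_CON\tAE1_vs_STABLE\tAE3_vs_CON\tAE3_vs_STABLE\tAE10_vs_CON\tAE10_vs_STABLE
BC004490\tFOS\t27.4\t28.6\t33.5\t34.9\t13.2\t13.7
BC015492\tIFI27\t12.3\t10.3\t13.1\t11.0\t21.6\t18.1
NM_001554\tCYR61\t12.0\t40.3\t11.2\t37.6\t11.7\t39.2
NM_001901\tCTGF\t35.7\t26.6\t36.9\t27.5\t59.3\t44.2
NM_003979\tGPRC5A\t21.2\t12.6\t19.2\t11.4\t75.8\t45.1
NM_006732\tFOSB\t21.7\t13.7\t40.1\t25.3\t35.6\t22.5
NM_133504\tDCN\t19.0\t17.2\t19.6\t17.8\t20.0\t18.1
XM_373497\tLOC387763\t41.4\t13.5\t46.4\t15.2\t41.3\t13.5
"""

_AECOPD_DOWN = """\
seq_id\tsymbol\tAE1_vs_CON\tAE1_vs_STABLE\tAE3_vs_CON\tAE3_vs_STABLE\tAE10_vs_CON\tAE10_vs_STABLE
AJ002102\tKIR2DS2\t3.7\t3.8\t7.4\t7.6\t4.2\t4.4
BC022407\tSH2D1B\t3.0\t3.7\t4.8\t5.9\t3.1\t3.8
BC066595\tSH2D1B\t3.6\t3.2\t9.9\t8.9\t3.6\t3.2
BC100911\tCD8B\t11.2\t4.4\t16.0\t6.3\t7.9\t3.1
NM_001004698\tOR2W5\t3.7\t3.1\t4.7\t4.0\t3.7\t3.1
NM_004931\tCD8B\t10.3\t5.3\t11.5\t5.9\t6.6\t3.4
NM_031950\tKSP37\t4.8\t5.0\t9.8\t10.2\t3.0\t3.1
NM_201633\tTCF7\t15.6\t5.6\t30.4\t10.8\t8.9\t3.2
"""

# --- Trajectory examples ----------------------------------------------------
# Two-step fold pairs (AE3 vs AE1, AE10 vs AE3) of the strongest genes of
# each dynamic pattern; the direction of each step follows the pattern.

_TRAJECTORY = """\
seq_id\tsymbol\tpattern\tstep1_fold\tstep2_fold
NM_000032\tALAS2\tdown-down\t6.4\t6.5
BC099627\tEPB42\tdown-down\t9.9\t4.4
BC027890\tCA1\tdown-down\t21.6\t5.1
AK127453\tNA\tdown-up\t4.7\t5.7
NM_003944\tSELENBP1\tdown-up\t5.6\t4.1
BC090921\tMYH9\tdown-up\t6.2\t4.1
NM_181717\tHCG27\tup-down\t4.1\t7.3
NM_177551\tGPR109A\tup-down\t4.3\t7.5
NM_006018\tGPR109B\tup-down\t4.4\t5.1
AF249277\tMTHFS\tup-down\t4.6\t5.3
AY234180\tBCL2A1\tup-down\t5.2\t4.0
BC010952\tPI3\tup-down\t6.0\t4.4
NM_002243\tKCNJ15\tup-down\t7.0\t4.8
Z15108\tPRKCZ\tup-up\t2.0\t2.8
BC037798\tCGI-38\tup-up\t2.0\t2.4
NM_001033581\tPRKCZ\tup-up\t2.1\t2.8
NM_007168\tABCA8\tup-up\t2.1\t4.0
AK022468\tSORBS1\tup-up\t2.3\t3.5
NM_006403\tNEDD9\tup-up\t2.3\t2.2
NM_023037\tFRY\tup-up\t2.3\t2.1
NM_016730\tFOLR1\tup-up\t3.0\t11.7
"""

# Signed stable-relative fold values at exacerbation days 1, 3, 10
# (negative = below the stable-COPD group).

_STABLE_RELATIVE = """\
seq_id\tsymbol\tpattern\tAE1\tAE3\tAE10
NM_000032\tALAS2\tdown-down\t17.64\t2.76\t-2.37
BC099627\tEPB42\tdown-down\t10.02\t1.01\t-4.37
BC027890\tCA1\tdown-down\t103.93\t4.81\t-1.06
AK127453\tNA\tdown-up\t-1.69\t-7.90\t-1.38
NM_003944\tSELENBP1\tdown-up\t3.97\t-1.41\t2.92
BC090921\tMYH9\tdown-up\t-1.36\t-8.40\t-2.04
NM_181717\tHCG27\tup-down\t1.09\t4.47\t-1.63
NM_177551\tGPR109A\tup-down\t4.12\t17.79\t2.36
NM_006018\tGPR109B\tup-down\t2.64\t11.64\t2.28
AF249277\tMTHFS\tup-down\t4.51\t20.75\t3.95
AY234180\tBCL2A1\tup-down\t2.38\t12.45\t3.11
BC010952\tPI3\tup-down\t1.03\t6.20\t1.42
NM_002243\tKCNJ15\tup-down\t2.25\t15.78\t3.26
Z15108\tPRKCZ\tup-up\t-1.25\t1.61\t4.46
BC037798\tCGI-38\tup-up\t-5.87\t-2.86\t-1.18
NM_001033581\tPRKCZ\tup-up\t-1.61\t1.30\t3.64
NM_007168\tABCA8\tup-up\t-1.27\t1.68\t6.69
AK022468\tSORBS1\tup-up\t1.28\t2.92\t10.30
NM_006403\tNEDD9\tup-up\t2.43\t5.57\t12.15
NM_023037\tFRY\tup-up\t-1.11\t2.08\t4.34
NM_016730\tFOLR1\tup-up\t-4.20\t-1.39\t8.39
"""

#: Per-patient DESS totals of the five study groups (six patients each).
DESS_TOTALS: dict[str, list[int]] = {
    "CON": [0, 4, 8, 4, 3, 0],
    "STABLE": [30, 27, 35, 55, 38, 47],
    "AE1": [100, 81, 86, 70, 80, 97],
    "AE3": [78, 66, 76, 51, 71, 81],
    "AE10": [43, 46, 36, 30, 35, 30],
}

#: DESS group means over the exacerbation time course (days 1, 3, 10).
DESS_AE_MEANS: tuple[float, float, float] = (85.7, 70.5, 36.7)

#: Clinical lung function of the exacerbation arm: FEV1 as % of predicted.
FEV1_PRED_AECOPD: list[float] = [42, 27, 33, 61, 55, 60]

#: FEV1/FVC % of the same six exacerbation patients.
FEV1_FVC_AECOPD: list[float] = [40, 36, 28, 48, 69, 56]


def _read(text: str) -> pd.DataFrame:
    return pd.read_csv(io.StringIO(text), sep="\t")


def _to_records(wide: pd.DataFrame, direction: str, labels: list[str]) -> pd.DataFrame:
    long = wide.melt(
        id_vars=["seq_id"], value_vars=labels, var_name="pair", value_name="ratio"
    )
    long["direction"] = direction
    long = long.rename(columns={"seq_id": "gene_id"})
    return long[["gene_id", "pair", "ratio", "direction"]]


def copd_panel_records() -> pd.DataFrame:
    """Long-format fold-change records of the COPD-specific worked example."""
    labels = [c.label for c in COPD_COMPARISONS]
    return pd.concat(
        [
            _to_records(_read(_COPD_UP), UP, labels),
            _to_records(_read(_COPD_DOWN), DOWN, labels),
        ],
        ignore_index=True,
    )


def aecopd_panel_records() -> pd.DataFrame:
    """Long-format fold-change records of the AECOPD-specific worked example."""
    labels = [c.label for c in AECOPD_COMPARISONS]
    return pd.concat(
        [
            _to_records(_read(_AECOPD_UP), UP, labels),
            _to_records(_read(_AECOPD_DOWN), DOWN, labels),
        ],
        ignore_index=True,
    )


def panel_symbols() -> dict[str, str]:
    """Row id -> gene symbol for both panel examples."""
    frames = [_read(t) for t in (_COPD_UP, _COPD_DOWN, _AECOPD_UP, _AECOPD_DOWN)]
    out: dict[str, str] = {}
    for f in frames:
        out.update(dict(zip(f["seq_id"], f["symbol"])))
    return out


def trajectory_examples() -> pd.DataFrame:
    """Two-step fold pairs with their known dynamic pattern."""
    return _read(_TRAJECTORY)


def trajectory_step_records() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The example fold pairs as two long-format step record tables."""
    wide = _read(_TRAJECTORY)
    d1 = wide["pattern"].str.split("-").str[0]
    d2 = wide["pattern"].str.split("-").str[1]
    step1 = pd.DataFrame(
        {"gene_id": wide["seq_id"], "pair": "AE3_vs_AE1",
         "ratio": wide["step1_fold"], "direction": d1}
    )
    step2 = pd.DataFrame(
        {"gene_id": wide["seq_id"], "pair": "AE10_vs_AE3",
         "ratio": wide["step2_fold"], "direction": d2}
    )
    return step1, step2


def stable_relative_trajectories() -> pd.DataFrame:
    """Signed stable-relative fold values at the three exacerbation days."""
    return _read(_STABLE_RELATIVE)
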