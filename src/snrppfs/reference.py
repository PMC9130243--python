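"""Published reference values for the 38-gene COAD signature.

Differential-expression and ROC reference table for the 38-gene colon
adenocarcinoma signature (tumor vs normal, combined TCGA/GTEx cohort of
289 tumors and 348 normals), on the log2(normalized count + 1) scale.
``stage_positive`` marks genes reported as positively correlated with
tumor stage (Pearson p < 0.05); ``survival_trend`` marks genes with a
univariate survival association at 0.05 < p < 0.1.

Used as a worked-example input: on log2 data the log fold change is the
difference of the reported group means, logFC = AveExpr(T) - AveExpr(N).
"""

from __future__ import annotations

import io

import pandas as pd

_TABLE = """\
gene_id\tlogFC\tave_expr_tumor\tave_expr_normal\tadj_p\tspecificity\tsensitivity\tauc\tstage_positive\tsurvival_trend
MMP7\t8.597\t10.269\t1.672\t2.24e-247\t98.9\t97.2\t0.994\t0\t0
KRT80\t7.498\t10.622\t3.124\t1.62e-317\t99.7\t99.0\t0.998\t1\t0
NOTUM\t7.363\t8.637\t1.274\t2.09e-175\t98.6\t95.5\t0.993\t1\t0
TNS4\t6.979\t12.162\t5.183\t9.91e-181\t98.3\t91.7\t0.987\t0\t0
S100P\t6.859\t12.859\t6.000\t2.83e-162\t91.7\t96.5\t0.978\t0\t0
SERPINB5\t6.676\t10.504\t3.829\t1.35e-162\t93.4\t91.0\t0.970\t1\t0
GRIN2D\t6.441\t10.372\t3.931\t1.59e-267\t96.8\t98.3\t0.996\t1\t0
UBE2C\t6.256\t11.824\t5.568\t2.34e-138\t96.0\t97.2\t0.993\t1\t0
RRM2\t6.203\t12.360\t6.157\t2.62e-128\t93.1\t98.6\t0.987\t0\t0
SAPCD2\t6.107\t11.959\t5.852\t1.36e-134\t96.3\t95.5\t0.992\t0\t0
VWA2\t6.032\t9.438\t3.406\t1.29e-227\t96.8\t95.5\t0.993\t0\t0
TPX2\t6.020\t12.635\t6.615\t1.96e-149\t95.4\t98.3\t0.994\t0\t0
WNT2\t5.954\t8.294\t2.341\t6.37e-216\t98.9\t93.8\t0.993\t0\t0
TOP2A\t5.555\t13.049\t7.494\t2.35e-141\t94.8\t96.5\t0.991\t1\t0
STRA6\t5.416\t7.839\t2.423\t4.36e-175\t98.3\t91.3\t0.981\t0\t0
OTX1\t5.411\t6.538\t1.127\t1.21e-222\t98.9\t93.4\t0.985\t0\t0
TRIM29\t5.307\t11.420\t6.113\t1.93e-195\t98.6\t92.0\t0.990\t0\t0
INHBA\t5.167\t10.480\t5.313\t3.06e-167\t96.8\t92.4\t0.982\t1\t0
SGOL1\t5.057\t8.763\t3.707\t1.11e-146\t99.7\t93.1\t0.989\t0\t0
TRIB3\t4.798\t11.587\t6.789\t1.96e-218\t97.1\t98.6\t0.996\t1\t1
TRIP13\t4.755\t10.238\t5.484\t1.35e-204\t97.7\t99.7\t0.997\t0\t0
TESC\t4.410\t10.367\t5.957\t2.79e-162\t95.1\t90.7\t0.954\t0\t0
ZWINT\t4.361\t11.312\t6.951\t5.32e-124\t90.8\t95.5\t0.976\t0\t0
SALL4\t4.249\t7.514\t3.265\t8.32e-158\t96.8\t90.7\t0.972\t1\t0
SPTBN2\t4.032\t10.730\t6.699\t5.31e-219\t98.3\t99.0\t0.993\t1\t0
RP11-386G11.5\t3.577\t5.779\t2.202\t7.02e-165\t96.3\t93.1\t0.984\t1\t0
TMEM97\t3.373\t11.728\t8.355\t1.33e-164\t96.8\t95.5\t0.992\t0\t0
TOMM34\t3.230\t12.094\t8.865\t1.15e-167\t99.4\t93.1\t0.991\t1\t0
TMEM206\t2.650\t9.031\t6.381\t1.57e-180\t98.9\t96.2\t0.996\t1\t0
WDR43\t2.578\t11.841\t9.263\t6.30e-148\t97.4\t99.7\t0.996\t1\t0
TMEFF2\t-3.729\t1.225\t4.954\t2.34e-167\t92.8\t93.4\t0.966\t0\t0
STMN4\t-4.236\t1.416\t5.651\t6.62e-161\t94.5\t91.3\t0.962\t0\t1
FAM135B\t-4.303\t1.583\t5.885\t4.34e-165\t96.0\t90.3\t0.966\t0\t1
GLP2R\t-4.818\t4.532\t9.349\t2.26e-175\t98.0\t98.3\t0.985\t0\t0
RERGL\t-4.894\t1.734\t6.628\t4.72e-163\t90.5\t93.1\t0.968\t0\t0
SFRP5\t-6.143\t2.305\t8.448\t4.49e-164\t96.0\t90.0\t0.964\t0\t0
SCN7A\t-6.757\t3.803\t10.560\t2.82e-157\t93.7\t90.7\t0.969\t0\t0
PLP1\t-7.039\t3.251\t10.290\t4.04e-181\t96.8\t95.5\t0.979\t0\t0
"""


def signature_reference_table() -> pd.DataFrame:
    """The published 38-gene DE/ROC reference table as a DataFrame."""
    df = pd.read_csv(io.StringIO(_TABLE), sep="\t")
    df["stage_positive"] = df["stage_positive"].astype(bool)
    df["survival_trend"] = df["survival_trend"].astype(bool)
    return df
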