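"""Published reference data for the mOSN NMD-target analyses.

Two small tables that downstream statistics consume as inputs:

``HIGH_CONFIDENCE_TARGETS``
    The published table of 52 high-confidence UPF3B-dependent NMD target
    mRNAs in mOSNs: gene symbol, log2 fold change (KO/WT), adjusted
    p-value, dEJ and uORF calls (YES/NO), and 3'UTR length in nt.

``PRIOR_NMD_TARGETS``
    The 11 previously reported likely mouse NMD target mRNAs that overlap
    the high-confidence set (each has at least one known NMD-inducing
    feature plus experimental evidence of NMD sensitivity from earlier
    studies in other tissues/cell lines).

``MOSN_DOMINANCE_COUNTS``
    Reported per-genotype counts of mOSNs whose dominant Olfr gene belongs
    to the 78 Olfr genes downregulated after Upf3b loss, over all mOSNs.
"""

from __future__ import annotations

import pandas as pd

# symbol, log2fc (KO/WT), padj, dEJ, uORF, 3'UTR length (nt)
_ROWS = [
    ("Prelid3a", 1.099967, 0.003745, "YES", "NO", 1572),
    ("1700025G04Rik", 0.662926, 0.012989, "NO", "YES", 8870),
    ("6030419C18Rik", 0.73232, 0.036112, "NO", "YES", 55),
    ("9330159F19Rik", 0.542375, 0.017617, "NO", "YES", 3408),
    ("Adcy6", 2.587005, 0.002078, "NO", "YES", 2356),
    ("Cdh24", 1.560901, 0.001303, "NO", "YES", 121),
    ("Fam84b", 0.719841, 0.001704, "NO", "YES", 3969),
    ("Inpp5f", 1.178064, 0.043839, "NO", "YES", 949),
    ("Lrp2", 2.504276, 0.008534, "NO", "YES", 1305),
    ("Mafg", 0.577538, 0.046713, "NO", "YES", 4167),
    ("Plxnc1", 2.322167, 0.048567, "NO", "YES", 2320),
    ("Prdm4", 0.420203, 0.027945, "NO", "YES", 1160),
    ("Ptch1", 0.768864, 0.01088, "NO", "YES", 3205),
    ("Ptger2", 3.032221, 0.035664, "NO", "YES", 1825),
    ("Sash3", 2.352656, 0.033245, "NO", "YES", 1309),
    ("Serpinb11", 1.991555, 0.002719, "NO", "YES", 468),
    ("Snx33", 1.512032, 0.012417, "NO", "YES", 1258),
    ("Zfp36", 1.802697, 0.025165, "NO", "YES", 774),
    ("Agap2", 1.264604, 0.00099, "NO", "NO", 1357),
    ("Aox2", 1.36834, 0.018035, "NO", "NO", 1640),
    ("Atp10d", 3.315656, 0.017617, "NO", "NO", 2384),
    ("Bhlhe40", 1.435423, 0.000192, "NO", "NO", 1593),
    ("Btg2", 1.281148, 0.000173, "NO", "NO", 2199),
    ("Cybrd1", 2.372842, 0.002733, "NO", "NO", 4269),
    ("Cyth4", 2.162221, 0.045105, "NO", "NO", 1455),
    ("Ermn", 1.686519, 0.005793, "NO", "NO", 2641),
    ("Fmo2", 2.02039, 0.014815, "NO", "NO", 2411),
    ("Gab2", 0.98414, 0.003018, "NO", "NO", 3927),
    ("Gdf11", 1.429234, 0.005353, "NO", "NO", 2811),
    ("Gldn", 2.115908, 0.045841, "NO", "NO", 2970),
    ("Hk2", 2.296045, 0.033161, "NO", "NO", 2285),
    ("Lbh", 1.417311, 0.024315, "NO", "NO", 2498),
    ("Luc7l", 0.492061, 8.19e-05, "NO", "NO", 3738),
    ("Map3k9", 0.79841, 0.021555, "NO", "NO", 1029),
    ("Msrb3", 1.668851, 0.033388, "NO", "NO", 2972),
    ("Neurl3", 1.966306, 0.00546, "NO", "NO", 1763),
    ("Notch2", 1.68375, 0.047733, "NO", "NO", 2917),
    ("Plekha5", 0.608634, 0.004216, "NO", "NO", 3461),
    ("Rab43", 1.033148, 0.0151, "NO", "NO", 3737),
    ("Rac2", 3.029035, 0.038392, "NO", "NO", 2319),
    ("Raver2", 1.921185, 0.027779, "NO", "NO", 1892),
    ("Rflnb", 0.755198, 0.017617, "NO", "NO", 2716),
    ("Sik1", 2.027635, 1.48e-06, "NO", "NO", 2035),
    ("Slc38a6", 1.21151, 0.025847, "NO", "NO", 1512),
    ("Slc5a1", 2.563582, 0.00527, "NO", "NO", 1868),
    ("Swap70", 1.863436, 0.009993, "NO", "NO", 2169),
    ("Tgm2", 2.395934, 0.042993, "NO", "NO", 1399),
    ("Themis2", 3.496025, 0.015464, "NO", "NO", 1053),
    ("Tmprss2", 2.167673, 0.005867, "NO", "NO", 1456),
    ("Tob2", 0.667082, 0.001453, "NO", "NO", 2459),
    ("Ywhag", 0.644673, 0.017707, "NO", "NO", 2586),
    ("Zcchc6", 0.512078, 0.003018, "NO", "NO", 1346),
]

PRIOR_NMD_TARGETS: frozenset[str] = frozenset(
    {
        "Atp10d",
        "Lbh",
        "Slc38a6",
        "Tgm2",
        "Notch2",
        "Ywhag",
        "Luc7l",
        "Ptch1",
        "1700025G04Rik",
        "Ptger2",
        "Msrb3",
    }
)

# (k mOSNs dominated by one of the 78 downregulated Olfr genes, n mOSNs)
MOSN_DOMINANCE_COUNTS = {"WT": (490, 3887), "KO": (328, 4654)}
IOSN_DOMINANCE_PERCENTS = {"WT": 8.0, "KO": 5.6}


def high_confidence_targets() -> pd.DataFrame:
    """Return the published 52-gene high-confidence NMD-target table."""
    return pd.DataFrame(
        _ROWS, columns=["symbol", "log2fc", "padj", "dej", "uorf", "utr3_len"]
    )


HIGH_CONFIDENCE_TARGETS = high_confidence_targets()
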