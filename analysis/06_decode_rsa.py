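"""HMM tone decoding and cross-level representational similarity.

Pseudo-trials (averaging size 8) are decoded with per-tone left-to-right
HMMs under leave-one-out CV, separately for the scalp and cortical-surface
channels; the two confusion matrices feed the RSA: off-diagonal Pearson
similarity plus Procrustes-aligned 2-D MDS of the tone confusion structure.
"""

import json

import numpy as np
import pandas as pd

from _common import RESULTS, SEED, get_clean_recording
from ffrkit.decode import decode_confusion, make_averaged_trials, track_features
from ffrkit.rsa import mds_procrustes

AVERAGING = 4


def main():
    rec = get_clean_recording()
    cms = {}
    for label in ("Cz", "PAC_surface"):
        waves, labels = make_averaged_trials(rec, AVERAGING, seed=SEED,
                                             channel=label)
        feats = [track_features(w, rec.fs, rec.t0_ms) for w in waves]
        cm = decode_confusion(feats, labels, cv_scheme="loo", seed=SEED,
                              averaging_size=AVERAGING)
        cms[label] = cm
        pd.DataFrame(cm.matrix, index=cm.labels, columns=cm.labels).to_csv(
            RESULTS / f"confusion_{label}.tsv", sep="\t")
        print(f"{label}: decoding accuracy {cm.accuracy:.3f} "
              f"({int(np.trace(cm.counts))}/{int(cm.counts.sum())} "
              f"pseudo-trials)")
    rsa = mds_procrustes(list(cms.values()), list(cms))
    (RESULTS / "rsa.json").write_text(json.dumps({
        "labels": rsa.labels,
        "r": np.round(rsa.r, 4).tolist(),
        "p": np.round(rsa.p, 4).tolist(),
        "procrustes_disparity": [round(d, 4) for d in rsa.disparities],
        "mds_coords": [np.round(c, 4).tolist() for c in rsa.coords],
    }, indent=1))
    r, p = rsa.r[0, 1], rsa.p[0, 1]
    print(f"Scalp vs cortex confusion similarity: r = {r:.3f} (p = {p:.4f}; "
          "NaN when decoding is error-free), Procrustes disparity "
          f"{rsa.disparities[1]:.4f}")


if __name__ == "__main__":
    main()
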