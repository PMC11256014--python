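#!/usr/bin/env python
"""Chemical-space workflow on a synthetic suspect list.

Pre-filters a small suspect table on composition (C and N/O present) and
monoisotopic mass (>= 100 Da), runs PCA on a synthetic descriptor matrix
(a stand-in for an external descriptor computation), selects maximally
spread representatives in the PC1-PC2 plane, and projects a second
compound set into the fitted space.

Writes results/chemspace/.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from lodie.chemspace import filter_suspects, fit_pca, project, select_representatives

OUT = Path("results/chemspace")
SEED = 2024

SUSPECTS = pd.DataFrame(
    {
        "compound_id": [
            "water", "glycine", "caffeine", "atrazine", "ibuprofen",
            "benzene", "urea", "carbamazepine", "nacl", "diuron",
        ],
        "formula": [
            "H2O", "C2H5NO2", "C8H10N4O2", "C8H14ClN5", "C13H18O2",
            "C6H6", "CH4N2O", "C15H12N2O", "NaCl", "C9H10Cl2N2O",
        ],
    }
)


def synthetic_descriptors(ids, n_desc=25, seed=SEED):
    """Synthetic stand-in for an externally computed descriptor matrix."""
    rng = np.random.default_rng(seed)
    latent = rng.normal(size=(len(ids), 3))
    mix = rng.normal(size=(3, n_desc))
    X = latent @ mix + rng.normal(0, 0.5, size=(len(ids), n_desc))
    df = pd.DataFrame(X, columns=[f"desc{i:02d}" for i in range(n_desc)])
    df.insert(0, "compound_id", ids)
    return df


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    kept, rejected = filter_suspects(SUSPECTS)
    print(f"suspect pre-filter: {len(kept)}/{len(SUSPECTS)} retained "
          f"({', '.join(kept.compound_id)})")
    for row in rejected.itertuples(index=False):
        print(f"  rejected {row.compound_id}: {row.reason}")

    pool = [f"S{i:04d}" for i in range(300)]
    desc = synthetic_descriptors(pool)
    model, scores = fit_pca(desc, n_components=2)
    r1, r2 = model.explained_variance_ratio
    print(f"PCA: PC1 {r1 * 100:.1f}%, PC2 {r2 * 100:.1f}% of descriptor variance")
    chosen = select_representatives(scores, 30)
    print(f"selected {len(chosen)} representatives by farthest-point sampling")

    newcomers = synthetic_descriptors([f"N{i:03d}" for i in range(50)], seed=SEED + 1)
    projected = project(model, newcomers)
    print(f"projected {len(projected)} new compounds into the fitted space")

    kept.to_csv(OUT / "suspects_retained.csv", index=False)
    rejected.to_csv(OUT / "suspects_rejected.csv", index=False)
    scores.to_csv(OUT / "scores.csv", index=False)
    pd.DataFrame({"compound_id": chosen,
                  "selection_rank": np.arange(1, len(chosen) + 1)}
                 ).to_csv(OUT / "selection.csv", index=False)
    projected.to_csv(OUT / "projected_scores.csv", index=False)
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
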