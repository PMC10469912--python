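"""UMAP embedding of the residual features (k=15, cosine metric).

Writes results/analysis/umap_coordinates.csv and a scatter plot per design.
"""

import warnings

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

import earmorph as em
from common import RESULTS, SEED, build_state


def main() -> None:
    out = RESULTS / "analysis"
    out.mkdir(parents=True, exist_ok=True)
    warnings.filterwarnings("ignore")
    training, _, state = build_state()
    fits = em.pipeline.fit_component_models(state)
    res = em.pipeline.residuals_for(
        fits, state.shapespace.scores, state.records, "marginal"
    )
    scores, _ = em.compute_patient_scores(training)
    frames = []
    for design_id in ("1", "2.1"):
        spec = em.DesignSpec.default(design_id)
        feats, labels = em.assemble_features(res, state.records, spec, scores)
        coords = em.umap_embed(feats.to_numpy(dtype=float), seed=SEED)
        frame = pd.DataFrame(
            {"design": design_id, "x": coords[:, 0], "y": coords[:, 1], "label": labels}
        )
        frames.append(frame)
        fig, ax = plt.subplots(figsize=(5, 4))
        for label, sub in frame.groupby("label"):
            ax.scatter(sub["x"], sub["y"], s=8, label=label, alpha=0.7)
        ax.legend(markerscale=2, fontsize=8)
        ax.set_title(f"UMAP, design {design_id} (k=15, cosine)")
        fig.tight_layout()
        fig.savefig(out / f"umap_design_{design_id.replace('.', '_')}.png", dpi=120)
        plt.close(fig)
        print(f"design {design_id}: embedded {len(frame)} ears")
    pd.concat(frames).to_csv(out / "umap_coordinates.csv", index=False)


if __name__ == "__main__":
    main()
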