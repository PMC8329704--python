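"""Model/Results interface over the analysis pipeline.

:class:`NfbLearningModel` is built from a cohort (real or simulated) and
its :meth:`~NfbLearningModel.fit` runs feature extraction, screening and
LOOCV prediction, returning an :class:`NfbLearningResults` that carries the
learning indices, the screened correlates with their inference, the
prediction report and a ``summary()`` table, with plotting attached.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .nfb_engine import FeedbackConfig
from .pipeline import PipelineConfig, run_pipeline
from .synthgen import CohortConfig, generate_cohort

__all__ = ["NfbLearningModel", "NfbLearningResults"]


class NfbLearningModel:
    """Multimodal prediction model of neurofeedback learning ability.

    Parameters
    ----------
    dataset : CohortDataset
        The multimodal cohort (training runs, resting EEG, fMRI volumes,
        morphometry maps, covariates).
    feedback_config : FeedbackConfig, optional
        Parameters of the online SMR power computation used to derive the
        learning index.
    """

    def __init__(self, dataset, feedback_config: FeedbackConfig | None = None):
        self.dataset = dataset
        self.feedback_config = feedback_config

    @classmethod
    def from_cohort_dir(cls, path, **kwargs) -> "NfbLearningModel":
        from .io import load_cohort
        return cls(load_cohort(path), **kwargs)

    @classmethod
    def simulate(cls, config: CohortConfig | None = None, seed: int | None = None,
                 **kwargs) -> tuple["NfbLearningModel", object]:
        """Simulate a synthetic cohort; returns ``(model, ground_truth)``."""
        cfg = config or CohortConfig()
        if seed is not None:
            cfg = CohortConfig(**{**cfg.__dict__, "seed": seed})
        dataset, gt = generate_cohort(cfg)
        return cls(dataset, **kwargs), gt

    def fit(self, config: PipelineConfig | None = None,
            **config_overrides) -> "NfbLearningResults":
        """Run the full analysis; keyword overrides update the config."""
        cfg = config or PipelineConfig()
        if config_overrides:
            cfg = PipelineConfig(**{**cfg.__dict__, **config_overrides})
        bundle = run_pipeline(self.dataset, cfg)
        return NfbLearningResults(self, bundle)


class NfbLearningResults:
    """Fitted results: learning indices, screened correlates, predictions."""

    def __init__(self, model: NfbLearningModel, bundle: dict):
        self.model = model
        self._bundle = bundle
        self.config = bundle["config"]
        self.li = bundle["li"]["li"].to_numpy()
        self.li_table = bundle["li"]
        self.li_normality_p = bundle["li_normality_p"]
        self.features = bundle.get("features")
        self.screens = bundle.get("screens")
        pred = bundle.get("prediction", {})
        self.feature_sets = pred.get("feature_sets")
        self.reports = pred.get("reports", {})

    # ------------------------------------------------------------------
    @property
    def selected_eeg(self) -> pd.DataFrame:
        rows = [{"feature": r.feature, "rho": r.rho, "p": r.p, "q": r.q,
                 "selected": r.selected} for r in self.screens["eeg"]]
        return pd.DataFrame(rows)

    def cluster_table(self, modality: str) -> pd.DataFrame:
        """Significant clusters of a map modality (gmv, wmv, alff)."""
        rows = []
        for contrast, sm in zip(("positive", "negative"), self.screens[modality]):
            for c in sm.clusters:
                rows.append({"modality": modality, "contrast": contrast,
                             "size": c.size, "peak_t": c.peak_t,
                             "peak_ijk": c.peak_ijk})
        return pd.DataFrame(rows)

    def prediction_frame(self) -> pd.DataFrame:
        return pd.concat([r.to_frame() for r in self.reports.values()],
                         ignore_index=True)

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = ["NFB learning prediction summary",
                 "=" * 48,
                 f"participants: {len(self.li)}",
                 f"positive LI: {int((self.li > 0).sum())}/{len(self.li)}",
                 f"LI Shapiro-Wilk p: {self.li_normality_p:.4g}", ""]
        if self.screens is not None:
            n_eeg = sum(r.selected for r in self.screens["eeg"])
            n_fc = sum(r.selected for r in self.screens["fc"])
            lines.append(f"selected EEG cells (FDR): {n_eeg}")
            for mod in ("gmv", "wmv", "alff"):
                pos, neg = self.screens[mod]
                lines.append(f"{mod} clusters: {len(pos.clusters)} positive, "
                             f"{len(neg.clusters)} negative")
            lines.append(f"selected FC edges: {n_fc}")
            lines.append("")
        if self.reports:
            df = self.prediction_frame()
            lines.append(df.to_string(index=False,
                                      float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)

    def plot_predictions(self, model: str | None = None, ax_grid=None):
        """Scatter of predicted vs actual (z-scored) LI per feature set."""
        import matplotlib.pyplot as plt

        name = model or next(iter(self.reports))
        rep = self.reports[name]
        sets = list(rep.predictions)
        if ax_grid is None:
            fig, axes = plt.subplots(1, len(sets), figsize=(3 * len(sets), 3),
                                     squeeze=False)
            axes = axes[0]
        else:
            axes = ax_grid
            fig = axes[0].figure
        li_z = (self.li - self.li.mean()) / self.li.std()
        for ax, sname in zip(axes, sets):
            p = rep.predictions[sname]
            ax.scatter(li_z, p, s=12, color="k")
            lim = [min(li_z.min(), p.min()), max(li_z.max(), p.max())]
            ax.plot(lim, lim, "r--", lw=0.8)
            ax.set_title(f"{sname}\nMAE={rep.mae[sname]:.3f} r={rep.r[sname]:.3f}",
                         fontsize=8)
            ax.set_xlabel("actual LI (z)")
        axes[0].set_ylabel("predicted LI (z)")
        fig.tight_layout()
        return fig
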