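"""Model-style front end: build from an ensemble of embeddings, fit, inspect.

``SpectralMetaVisualization`` wraps the spectral assessment/combination
pipeline the way statistical modelling packages wrap an estimator: the model
is constructed from data (an :class:`~metaviz.core.EmbeddingSet`, a mapping of
arrays, files on disk, or a raw data matrix run through the candidate
registry), and ``fit()`` returns a results object carrying the eigenscores,
the meta-distance, per-candidate summaries and rendering/plotting helpers.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import candidates as _candidates
from . import core, render as _render

__all__ = ["SpectralMetaVisualization", "MetaVisualizationResults"]


class SpectralMetaVisualization:
    """Spectral eigenscore model over K candidate visualizations.

    Parameters
    ----------
    embeddings : EmbeddingSet or mapping of name -> (n, 2) array
    weighting : {"spectral", "naive"}
        "spectral" weights each sample's consensus row by the eigenscores;
        "naive" averages candidates uniformly (the baseline the spectral
        weighting is compared against).
    on_degenerate : {"raise", "zero"}
        Policy for zero-norm distance rows (see ``normalize_distances``).
    """

    def __init__(self, embeddings, weighting: str = "spectral",
                 on_degenerate: str = "raise"):
        if isinstance(embeddings, core.EmbeddingSet):
            self.embeddings = embeddings
        elif isinstance(embeddings, Mapping):
            self.embeddings = core.EmbeddingSet(embeddings)
        else:
            raise TypeError("embeddings must be an EmbeddingSet or a mapping")
        if weighting not in ("spectral", "naive"):
            raise ValueError(f"unknown weighting {weighting!r}")
        self.weighting = weighting
        self.on_degenerate = on_degenerate

    @classmethod
    def from_files(cls, paths: Sequence, **kwargs) -> "SpectralMetaVisualization":
        """Build from delimited embedding files (one per candidate)."""
        from .io import read_embeddings

        return cls(read_embeddings(paths), **kwargs)

    @classmethod
    def from_data(
        cls,
        data: np.ndarray,
        specs=None,
        sample_ids=None,
        seed: int = 0,
        strict: bool = False,
        **kwargs,
    ) -> "SpectralMetaVisualization":
        """Build by running the candidate registry on a raw n x p data
        matrix (default: the 16-candidate registry)."""
        emb = _candidates.run_registry(
            data, specs, sample_ids=sample_ids, strict=strict, seed=seed
        )
        return cls(emb, **kwargs)

    def fit(self) -> "MetaVisualizationResults":
        matrices = self.embeddings.normalized_distances(self.on_degenerate)
        names = list(matrices)
        mats = [matrices[k] for k in names]
        scores = core.eigenscores(mats, candidates=names)
        if self.weighting == "spectral":
            meta = core.meta_distance(mats, scores)
        else:
            meta = core.naive_meta_distance(mats)
        return MetaVisualizationResults(self, matrices, scores, meta)


class MetaVisualizationResults:
    """Fitted eigenscores and meta-distance with summaries and rendering."""

    def __init__(self, model, normalized_distances, eigenscores, meta_distance):
        self.model = model
        self.normalized_distances: dict[str, core.NormalizedDistanceMatrix] = (
            normalized_distances
        )
        self.eigenscores: core.EigenscoreTable = eigenscores
        self.meta_distance: core.MetaDistance = meta_distance

    @property
    def sample_ids(self) -> np.ndarray:
        return self.meta_distance.sample_ids

    @property
    def candidates(self) -> list[str]:
        return list(self.eigenscores.candidates)

    def eigenscore_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.eigenscores.values,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.candidates,
        )

    def summary(self) -> pd.DataFrame:
        """Per-candidate eigenscore summary, ranked by median (the usual
        statistic for ranking and selecting candidate visualizations)."""
        df = self.eigenscore_frame()
        out = pd.DataFrame(
            {
                "mean_eigenscore": df.mean(),
                "median_eigenscore": df.median(),
                "cv_eigenscore": df.std(ddof=1) / df.mean(),
            }
        )
        out.index.name = "candidate"
        out = out.sort_values("median_eigenscore", ascending=False)
        out["rank"] = np.arange(1, len(out) + 1)
        return out

    def render(self, method: str = "umap", params: dict | None = None,
               seed: int = 0) -> _render.MetaVisualization:
        """Render the meta-visualization from the fitted meta-distance."""
        return _render.render_meta(self.meta_distance, method, params, seed)

    def plot(self, labels=None, method: str = "umap", seed: int = 0, ax=None):
        return _render.scatter(self.render(method=method, seed=seed),
                               labels=labels, ax=ax)
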