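"""End-to-end staging bundle: embedding + four OvR models + staging map.

Composes the token renderer, the skip-gram embedding, the dynamic-sampling
one-vs-rest stager and the decision-value logic into a single object that
goes from :class:`~nsclc_staging.records.PatientRecord` to
:class:`~nsclc_staging.decision.StagePrediction`, with plain-text
persistence (word2vec text embeddings plus a JSON checkpoint carrying
shapes, parameters and configuration).
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import spawn_seed
from .decision import StagePrediction, StagingMap, predict_stage
from .embeddings import SkipgramEmbedding
from .records import NormalRanges, PatientRecord, render_text
from .sampling import DynamicSamplingStager

__all__ = ["StagingBundle"]

_CHECKPOINT_VERSION = 1


class StagingBundle:
    """Trainable, serializable staging system.

    Parameters are forwarded to the embedding and stager components;
    ``seed`` derives independent streams for both.
    """

    def __init__(
        self,
        embedding_params: dict | None = None,
        stager_params: dict | None = None,
        staging_map: StagingMap | None = None,
        treatment_profile: str = "coarse",
        ranges: NormalRanges | None = None,
        seed: int = 0,
    ):
        self.embedding_params = dict(embedding_params or {})
        self.stager_params = dict(stager_params or {})
        self.staging_map = staging_map or StagingMap()
        self.treatment_profile = treatment_profile
        self.ranges = ranges or NormalRanges()
        self.seed = seed

    # -- training / prediction -------------------------------------------

    def fit(self, records: Sequence[PatientRecord]) -> "StagingBundle":
        corpus = [render_text(r, self.ranges) for r in records]
        self.embedding_ = SkipgramEmbedding(
            seed=spawn_seed(self.seed, "embedding"), **self.embedding_params
        ).fit(corpus)
        X = self.embedding_.transform(corpus)
        y = [r.stages for r in records]
        self.stager_ = DynamicSamplingStager(
            seed=spawn_seed(self.seed, "stager"), **self.stager_params
        ).fit(X, y)
        return self

    def predict(self, records: Sequence[PatientRecord]) -> list[StagePrediction]:
        self._check_fitted()
        corpus = [render_text(r, self.ranges) for r in records]
        conf = self.stager_.predict_confidences(self.embedding_.transform(corpus))
        return [
            predict_stage(
                rec.patient_id,
                {s: float(conf.iloc[i][s]) for s in conf.columns},
                self.staging_map,
                self.treatment_profile,
            )
            for i, rec in enumerate(records)
        ]

    def predict_confidences(self, records: Sequence[PatientRecord]) -> pd.DataFrame:
        self._check_fitted()
        corpus = [render_text(r, self.ranges) for r in records]
        return self.stager_.predict_confidences(self.embedding_.transform(corpus))

    def _check_fitted(self):
        if not hasattr(self, "stager_"):
            raise RuntimeError("StagingBundle is not fitted")

    # -- persistence -------------------------------------------------------

    def save(self, directory) -> None:
        """Write the bundle: embeddings in word2vec text format, all model
        parameters and configuration in one JSON checkpoint."""
        self._check_fitted()
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.embedding_.save_word2vec(directory / "embeddings.w2v.txt")
        models = {}
        for li, model in self.stager_.models_.items():
            w = model.get_weights()
            models[li] = {
                "kernels": [
                    {"shape": list(kw.shape), "weights": kw.tolist(), "bias": kb}
                    for kw, kb in w["kernels"]
                ],
                "fc_weights": w["fc_weights"].tolist(),
                "fc_bias": w["fc_bias"].tolist(),
                "n_dim": w["n_dim"],
            }
        checkpoint = {
            "version": _CHECKPOINT_VERSION,
            "seed": self.seed,
            "embedding_params": self.embedding_params,
            "stager_params": self.stager_params,
            "treatment_profile": self.treatment_profile,
            "staging_map": asdict(self.staging_map),
            "labels": list(self.stager_.labels),
            "sources": self.stager_.sources_,
            "cooccurrence": self.stager_.cooccurrence_.to_dict(),
            "models": models,
        }
        (directory / "checkpoint.json").write_text(json.dumps(checkpoint))
        self.stager_.cooccurrence_.to_csv(directory / "cooccurrence.csv")
        for li, log in self.stager_.logs_.items():
            if len(log):
                log.to_csv(directory / f"iterations_{li}.csv", index=False)

    @classmethod
    def load(cls, directory) -> "StagingBundle":
        directory = Path(directory)
        checkpoint = json.loads((directory / "checkpoint.json").read_text())
        if checkpoint["version"] != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {checkpoint['version']}")
        bundle = cls(
            embedding_params=checkpoint["embedding_params"],
            stager_params=checkpoint["stager_params"],
            staging_map=StagingMap(**checkpoint["staging_map"]),
            treatment_profile=checkpoint["treatment_profile"],
            seed=checkpoint["seed"],
        )
        bundle.embedding_ = SkipgramEmbedding.load_word2vec(
            directory / "embeddings.w2v.txt", **checkpoint["embedding_params"]
        )
        stager = DynamicSamplingStager(
            labels=checkpoint["labels"],
            seed=spawn_seed(checkpoint["seed"], "stager"),
            **checkpoint["stager_params"],
        )
        stager.models_ = {}
        stager.sources_ = checkpoint["sources"]
        stager.cooccurrence_ = pd.DataFrame(checkpoint["cooccurrence"])
        stager.logs_ = {}
        for li, payload in checkpoint["models"].items():
            model = stager._make_cnn(li, None)
            model.set_weights(
                {
                    "kernels": [
                        (np.array(k["weights"]), k["bias"]) for k in payload["kernels"]
                    ],
                    "fc_weights": np.array(payload["fc_weights"]),
                    "fc_bias": np.array(payload["fc_bias"]),
                    "n_dim": payload["n_dim"],
                }
            )
            stager.models_[li] = model
        bundle.stager_ = stager
        return bundle
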