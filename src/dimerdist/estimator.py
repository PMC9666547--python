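"""Scikit-learn style estimator wrapping network construction, training,
and contact inference.

``InterchainDistancePredictor`` is a fit/predict front end over the
library modules: ``fit`` trains the distogram network on a list of
examples, ``predict`` returns per-dimer distogram volumes, and
``predict_contacts`` converts them to ranked inter-chain contact maps.
Hyperparameters follow sklearn conventions (constructor args mirrored by
``get_params``/``set_params``; fitted state carries a trailing underscore),
so the estimator composes with ``sklearn.base.clone`` and model-selection
utilities that accept list-shaped X.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .infer import ContactScoreMap, contact_map_from_distogram, rank_contacts
from .nn.model import DistogramNetwork, DistogramPrediction, NetworkConfig, forward
from .train import TrainingExample, TrainingSchedule, train_loop


class InterchainDistancePredictor(BaseEstimator):
    """Trainable inter-chain distogram predictor.

    Parameters
    ----------
    total_conv_layers, filters, maxout_groups, se_reduction
        Architecture knobs; the defaults reproduce the published
        156-layer / 64-filter configuration.
    epochs
        Number of epochs actually run (truncates the 80-epoch two-phase
        schedule for desk-scale work); ``None`` runs the full schedule.
    seed
        Seeds both weight initialization and example shuffling.
    contact_threshold
        Distance (Angstrom) under which a residue pair counts as a contact.
    symmetrize_output
        Average homodimer score maps with their transpose.
    """

    def __init__(
        self,
        total_conv_layers: int = 156,
        filters: int = 64,
        maxout_groups: int = 2,
        se_reduction: int = 16,
        epochs: int | None = None,
        seed: int = 0,
        contact_threshold: float = 8.0,
        symmetrize_output: bool = True,
    ):
        self.total_conv_layers = total_conv_layers
        self.filters = filters
        self.maxout_groups = maxout_groups
        self.se_reduction = se_reduction
        self.epochs = epochs
        self.seed = seed
        self.contact_threshold = contact_threshold
        self.symmetrize_output = symmetrize_output

    # -- sklearn API ------------------------------------------------------

    def fit(self, X, y=None) -> "InterchainDistancePredictor":
        """Train on a list of ``TrainingExample`` (or (stack, labels) pairs).

        ``X`` may be a list of TrainingExample, or a list of FeatureStack
        with ``y`` a parallel list of (heavy_bins, cb_bins, mask) tuples.
        """
        examples = self._coerce_examples(X, y)
        config = NetworkConfig(
            total_conv_layers=self.total_conv_layers,
            filters=self.filters,
            maxout_groups=self.maxout_groups,
            se_reduction=self.se_reduction,
            seed=self.seed,
        )
        self.network_ = DistogramNetwork(config)
        self.schedule_ = TrainingSchedule()
        self.loss_trace_ = train_loop(
            self.network_,
            examples,
            schedule=self.schedule_,
            seed=self.seed,
            epochs=self.epochs,
        )
        self.n_examples_ = len(examples)
        return self

    def predict(self, X) -> list[DistogramPrediction]:
        """Distogram volumes for a list of FeatureStack (or TrainingExample)."""
        self._check_fitted()
        stacks = [x.stack if isinstance(x, TrainingExample) else x for x in X]
        return [forward(self.network_, s) for s in stacks]

    def predict_contacts(self, X) -> list[ContactScoreMap]:
        """Heavy-atom-head contact probability maps for each input."""
        return [
            contact_map_from_distogram(
                p,
                threshold=self.contact_threshold,
                symmetrize_output=self.symmetrize_output,
            )
            for p in self.predict(X)
        ]

    def rank(self, X, dedupe_symmetric: bool = True):
        """Ranked contact lists for each input."""
        return [
            rank_contacts(m, dedupe_symmetric=dedupe_symmetric)
            for m in self.predict_contacts(X)
        ]

    def score(self, X, y=None) -> float:
        """Negative mean training-style loss over ``X`` (higher is better)."""
        from .train import masked_cross_entropy

        examples = self._coerce_examples(X, y)
        losses = [
            masked_cross_entropy(pred, ex.heavy_bins, ex.cb_bins, ex.mask)
            for pred, ex in zip(self.predict(examples), examples)
        ]
        return -float(np.mean(losses))

    # -- helpers ----------------------------------------------------------

    @staticmethod
    def _coerce_examples(X, y) -> list[TrainingExample]:
        if y is None:
            if not all(isinstance(x, TrainingExample) for x in X):
                raise ValueError(
                    "without y, X must be a list of TrainingExample objects"
                )
            return list(X)
        return [
            TrainingExample(stack=stack, heavy_bins=hb, cb_bins=cb, mask=mask)
            for stack, (hb, cb, mask) in zip(X, y)
        ]

    def _check_fitted(self):
        if not hasattr(self, "network_"):
            raise RuntimeError("estimator is not fitted; call fit() first")
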