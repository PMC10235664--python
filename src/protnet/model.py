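"""Model/Results interface over the full analysis.

:class:`ProteomicNetworkModel` is built from a protein panel (and,
optionally, phenotypes); ``fit()`` runs preprocessing and module detection
and returns a :class:`ProteomicNetworkResults` carrying the partition,
eigenproteins, module membership and diagnostics, with association scans,
stability resampling and plotting as results methods.

Example
-------
>>> from protnet import ProteomicNetworkModel, simulate
>>> proteins, pheno, truth = simulate.generate_cohort(simulate.SimulationConfig())
>>> res = ProteomicNetworkModel(proteins, pheno).fit()
>>> print(res.summary())
>>> status = res.status_scan(tier="base")
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import association as assoc
from . import network as net
from . import preprocess as prep
from . import stability as stab
from .containers import (
    EigenproteinSet,
    ModulePartition,
    PhenotypeTable,
    ProteinMatrix,
    StabilityReport,
    ValidationError,
)


class ProteomicNetworkModel:
    """Weighted correlation-network model of a subjects x analytes panel.

    Parameters
    ----------
    proteins
        Raw panel (stage ``raw``); missingness filtering, imputation and the
        inverse-normal transform are applied by :meth:`fit`.  An already
        imputed or transformed panel is accepted and picked up mid-chain.
    phenotypes
        Optional phenotype table enabling the association scans.
    preprocess_config, network_config
        Stage settings; defaults reproduce the standard analysis (30 %
        missingness exclusion, Blom transform, unsigned beta = 4 network,
        TOM dissimilarity, minimum module size 5).
    """

    def __init__(
        self,
        proteins: ProteinMatrix,
        phenotypes: PhenotypeTable | None = None,
        preprocess_config: prep.PreprocessConfig | None = None,
        network_config: net.NetworkConfig | None = None,
    ) -> None:
        self.proteins = proteins
        self.phenotypes = phenotypes
        self.preprocess_config = preprocess_config or prep.PreprocessConfig()
        self.network_config = network_config or net.NetworkConfig()
        if phenotypes is not None:
            missing = proteins.subject_ids.difference(phenotypes.subject_ids)
            if len(missing):
                raise ValidationError(
                    f"subjects missing from phenotype table: {list(missing[:5])}"
                )

    @classmethod
    def from_dataframes(
        cls,
        proteins: pd.DataFrame,
        phenotypes: pd.DataFrame | None = None,
        limits: pd.DataFrame | None = None,
        **kwargs,
    ) -> "ProteomicNetworkModel":
        """Build from plain frames: proteins (subjects x analytes, NaN =
        missing), phenotypes indexed by subject, optional detection limits
        (index analyte, columns lower/upper)."""
        pm = ProteinMatrix(values=proteins.astype(float), limits=limits, stage="raw")
        pt = PhenotypeTable(phenotypes) if phenotypes is not None else None
        return cls(pm, pt, **kwargs)

    def fit(self) -> "ProteomicNetworkResults":
        """Run the pipeline: filter, impute, transform, build the network,
        detect modules, compute eigenproteins and kME."""
        excluded: list = []
        m = self.proteins
        if m.stage == "raw":
            m, excluded = prep.filter_by_missingness(m, self.preprocess_config)
            m = prep.impute(m)
        imputed = m if m.stage == "imputed" else None
        if m.stage == "imputed":
            m = prep.inverse_normal_transform(m, self.preprocess_config)

        cor = net.correlation_matrix(m)
        adjacency = net.soft_threshold_adjacency(cor, self.network_config)
        try:
            sf = net.scale_free_fit(adjacency)
        except ValidationError:
            sf = None
        if self.network_config.dissimilarity == "tom":
            dissim = 1.0 - net.topological_overlap(adjacency)
        else:
            dissim = 1.0 - adjacency
        partition = net.detect_modules(
            dissim, self.network_config, cor=cor, n_subjects=m.n_subjects
        )
        eigen = (
            net.eigenprotein_set(m, partition) if partition.n_modules else None
        )
        return ProteomicNetworkResults(
            model=self,
            transformed=m,
            imputed=imputed,
            excluded_analytes=excluded,
            correlation=cor,
            scale_free=sf,
            partition=partition,
            eigenproteins=eigen,
        )


@dataclass
class ProteomicNetworkResults:
    """Fitted network: partition, eigenproteins, diagnostics and scans."""

    model: ProteomicNetworkModel
    transformed: ProteinMatrix
    imputed: ProteinMatrix | None
    excluded_analytes: list
    correlation: pd.DataFrame
    scale_free: net.ScaleFreeFit | None
    partition: ModulePartition
    eigenproteins: EigenproteinSet | None
    _stability: StabilityReport | None = field(default=None, repr=False)

    @property
    def n_modules(self) -> int:
        return self.partition.n_modules

    def mean_abs_within_correlation(self, label: int) -> float:
        return net.mean_abs_within_correlation(
            self.correlation, self.partition.analytes_in(label)
        )

    # ------------------------------------------------------------------ scans
    def _require_phenotypes(self) -> PhenotypeTable:
        if self.model.phenotypes is None:
            raise ValidationError("model was built without phenotypes")
        return self.model.phenotypes

    def _require_eigen(self) -> EigenproteinSet:
        if self.eigenproteins is None:
            raise ValidationError("no modules were detected; nothing to scan")
        return self.eigenproteins

    def status_scan(self, tier: str = "base") -> list:
        """Current-vs-control contrast of every eigenprotein (Bonferroni
        across modules); the minimum-p module is flagged."""
        return assoc.scan_clusters_vs_status(
            self._require_eigen().scores, self._require_phenotypes(), tier
        )

    def symptom_scan(
        self,
        modules: list | None = None,
        tier: str = "base",
        contrast: str = "high",
        items: list | None = None,
    ) -> list:
        """Per-symptom contrast scan of the selected modules (default: the
        minimum-p module from the status scan)."""
        eigen = self._require_eigen()
        if modules is None:
            status = self.status_scan(tier="base")
            modules = [r.module for r in status if r.min_p_flag]
        cols = [m if isinstance(m, str) else f"M{m}" for m in modules]
        return assoc.scan_symptoms(
            eigen.scores[cols], self._require_phenotypes(), tier, contrast, items
        )

    # -------------------------------------------------------------- stability
    def stability(
        self,
        reference_module: int | list = 1,
        iterations: int = 1000,
        seed: int = 0,
    ) -> StabilityReport:
        """Split-half resampling of the reference module (label or analyte
        list); requires the imputed full-sample matrix."""
        if self.imputed is None:
            raise ValidationError(
                "stability needs the imputed matrix; fit from a raw/imputed panel"
            )
        ref = (
            self.partition.analytes_in(reference_module)
            if isinstance(reference_module, int)
            else list(reference_module)
        )
        cfg = stab.StabilityConfig(
            iterations=iterations,
            seed=seed,
            reference_module=ref,
            network=self.model.network_config,
        )
        self._stability = stab.run_stability(self.imputed, cfg)
        return self._stability

    # ---------------------------------------------------------------- summary
    def summary(self) -> str:
        lines = []
        lines.append("Proteomic correlation network")
        lines.append("=" * 64)
        cfg = self.model.network_config
        lines.append(
            f"analytes: {self.partition.assignment.size}"
            f" (excluded by missingness: {len(self.excluded_analytes)})"
            f"   subjects: {self.transformed.n_subjects}"
        )
        lines.append(
            f"network: unsigned, beta={cfg.beta:g}, dissimilarity={cfg.dissimilarity},"
            f" min module size {cfg.min_module_size}"
        )
        if self.scale_free is not None:
            lines.append(
                f"scale-free fit: R^2={self.scale_free.r_squared:.3f}"
                f" slope={self.scale_free.slope:.2f}"
            )
        lines.append("-" * 64)
        if self.partition.n_modules == 0:
            lines.append("no modules detected")
        else:
            lines.append(f"{'module':>8} {'size':>6} {'var.expl.':>10} {'mean |r|':>10}")
            for label, size in self.partition.module_sizes.items():
                ve = (
                    self.eigenproteins.variance_explained.get(f"M{label}", np.nan)
                    if self.eigenproteins
                    else np.nan
                )
                mr = self.mean_abs_within_correlation(int(label))
                lines.append(f"{label:>8} {size:>6} {ve:>10.3f} {mr:>10.3f}")
            lines.append(f"unassigned: {self.partition.n_unassigned}")
        lines.append("=" * 64)
        return "\n".join(lines)

    # ---------------------------------------------------------------- plotting
    def plot_dendrogram(self, ax=None):
        """Dendrogram of the clustering with module-colour leaf labels."""
        import matplotlib.pyplot as plt
        from scipy.cluster.hierarchy import dendrogram

        if self.partition.linkage is None:
            raise ValidationError("no dendrogram available")
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        dendrogram(self.partition.linkage, ax=ax, no_labels=True,
                   color_threshold=0.0)
        ax.set_ylabel("dissimilarity")
        return ax

    def plot_stability_frequencies(self, ax=None):
        """Bar plot of per-analyte inclusion frequencies (reference module)."""
        import matplotlib.pyplot as plt

        if self._stability is None:
            raise ValidationError("run .stability() first")
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        freqs = self._stability.frequencies.loc[self._stability.reference]
        freqs = freqs.sort_values(ascending=False)
        ax.bar(range(len(freqs)), 100 * freqs.to_numpy())
        ax.set_xticks(range(len(freqs)))
        ax.set_xticklabels(freqs.index, rotation=90, fontsize=6)
        ax.set_ylabel("% of clusterings")
        return ax
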