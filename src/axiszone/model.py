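"""Model/Results interface tying the zone-specificity stages together.

``ZoneSpecificityModel`` wraps a raw :class:`~axiszone.io.ZoneCountTable`
and a :class:`~axiszone.io.RunConfig`; ``fit()`` executes the stages in
order — low-expression filter, TMM normalization, one-vs-rest exact tests,
membership scoring — and returns a :class:`ZoneSpecificityResults`
carrying the per-(transcript, zone) estimates, the composite codes, the
category summary, a reproducibility manifest and plotting helpers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exact_test import one_vs_rest_tests
from .io import (
    RunConfig,
    ZoneCountTable,
    write_config,
    write_counts,
    write_results,
)
from .membership import (
    CategorySummary,
    assign_membership_all,
    summarize_categories,
)
from .normalization import (
    NormalizationResult,
    compute_cpm,
    cutoff_diagnostic,
    filter_low_expression,
    normalize,
)
from .simulate import SyntheticTruth, score_recovery

__all__ = ["ZoneSpecificityModel", "ZoneSpecificityResults", "RunManifest", "run_pipeline"]


@dataclasses.dataclass
class RunManifest:
    """Everything needed to reproduce a run byte-for-byte."""

    config: dict
    seed: int
    input_checksums: dict[str, str]
    n_detected: int
    n_kept: int
    n_tested: int
    n_restricted: int
    version: str = __version__

    def __post_init__(self) -> None:
        if not (self.n_kept <= self.n_detected and self.n_restricted <= self.n_kept):
            raise ValueError("manifest stage counts are inconsistent")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


class ZoneSpecificityModel:
    """Zone-specificity screen over an ordered axial count matrix.

    Parameters
    ----------
    table
        Raw counts, zones in anterior-to-posterior order.
    config
        Analysis parameters (filter cutoff, dispersion, FDR level, ...).
    """

    def __init__(self, table: ZoneCountTable, config: RunConfig | None = None):
        self.table = table
        self.config = config or RunConfig()
        if self.config.library_sizes is not None:
            table.library_sizes = np.asarray(self.config.library_sizes, dtype=np.int64)

    @classmethod
    def from_dataframe(
        cls,
        counts: pd.DataFrame,
        config: RunConfig | None = None,
        library_sizes=None,
    ) -> "ZoneSpecificityModel":
        """Build from a DataFrame indexed by transcript, zone columns in axial order."""
        table = ZoneCountTable(
            transcript_ids=[str(i) for i in counts.index],
            zone_labels=[str(c) for c in counts.columns],
            counts=counts.to_numpy(),
            library_sizes=library_sizes,
        )
        return cls(table, config)

    def fit(self) -> "ZoneSpecificityResults":
        """Run filter -> normalize -> test -> score and collect results."""
        cfg = self.config
        raw_cpm = compute_cpm(self.table.counts, self.table.library_sizes.astype(float))
        keep = filter_low_expression(raw_cpm, cfg.cpm_cutoff)
        if not keep.any():
            raise ValueError("low-expression filter removed every transcript")
        filtered = self.table.subset(keep)
        norm = normalize(filtered, trim_m=cfg.trim_m, trim_a=cfg.trim_a)
        records = one_vs_rest_tests(filtered, norm, cfg)
        codes = assign_membership_all(
            records,
            norm.cpm,
            filtered.transcript_ids,
            filtered.zone_labels,
            cfg.alpha,
        )
        summary = summarize_categories(codes)
        manifest = RunManifest(
            config=dataclasses.asdict(cfg),
            seed=cfg.seed,
            input_checksums={},
            n_detected=self.table.n_transcripts,
            n_kept=filtered.n_transcripts,
            n_tested=filtered.n_transcripts,
            n_restricted=summary.n_restricted,
        )
        return ZoneSpecificityResults(
            model=self,
            kept=keep,
            filtered_table=filtered,
            normalization=norm,
            records=records,
            codes=codes,
            category_summary=summary,
            manifest=manifest,
        )


@dataclasses.dataclass
class ZoneSpecificityResults:
    """Fitted zone-specificity screen.

    Attributes
    ----------
    records
        One row per (transcript, zone): logFC, p, BH q, score = -log10(p).
    codes
        Composite membership code per kept transcript ("none" if not
        restricted to any zone).
    category_summary
        Transcript counts per code.
    """

    model: ZoneSpecificityModel
    kept: np.ndarray
    filtered_table: ZoneCountTable
    normalization: NormalizationResult
    records: pd.DataFrame
    codes: pd.Series
    category_summary: CategorySummary
    manifest: RunManifest

    @property
    def cpm(self) -> pd.DataFrame:
        return self.normalization.cpm_frame(self.filtered_table.transcript_ids)

    def results_frame(self) -> pd.DataFrame:
        """Per-transcript table: normalized CPM, q-values, membership code."""
        zones = self.filtered_table.zone_labels
        wide_q = (
            self.records.pivot(index="transcript_id", columns="zone", values="q_value")
            .reindex(index=self.filtered_table.transcript_ids, columns=zones)
        )
        out = pd.DataFrame({"transcript_id": self.filtered_table.transcript_ids})
        for i, z in enumerate(zones):
            out[f"cpm_{z}"] = self.normalization.cpm[:, i]
        for z in zones:
            out[f"q_{z}"] = wide_q[z].to_numpy()
        out["code"] = self.codes.to_numpy()
        return out

    def recovery(self, truth: SyntheticTruth) -> pd.DataFrame:
        """Compare assigned codes with a planted synthetic truth."""
        return score_recovery(self.codes, truth)

    def summary(self) -> str:
        """Human-readable run summary in the spirit of a fit report."""
        m = self.manifest
        zones = self.filtered_table.zone_labels
        lines = [
            "Zone-specificity screen",
            "=" * 54,
            f"zones (anterior -> posterior): {', '.join(zones)}",
            f"transcripts detected:  {m.n_detected}",
            f"kept after CPM filter: {m.n_kept} (cutoff {self.model.config.cpm_cutoff})",
            f"axially restricted:    {m.n_restricted} "
            f"(q <= {self.model.config.alpha}, logFC > 0)",
            f"distinct categories:   {self.category_summary.n_categories} "
            f"({self.category_summary.n_multi} multi-zone)",
            "",
            "TMM normalization factors:",
        ]
        for z, f, e in zip(
            zones,
            self.normalization.normalization_factors,
            self.normalization.effective_library_sizes,
        ):
            lines.append(f"  zone {z}: factor {f:.4f}  effective size {e:,.0f}")
        lines.append("")
        lines.append("top categories (code: transcripts):")
        for _, row in self.category_summary.to_frame().head(10).iterrows():
            lines.append(f"  {row['code']}: {row['n_transcripts']}")
        return "\n".join(lines)

    # ---- plotting ------------------------------------------------------

    def plot_qc(self, path: str | Path | None = None):
        """Box, density and MDS panels of per-zone log2 CPM distributions."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from scipy.stats import gaussian_kde

        logc = np.log2(self.normalization.cpm + self.model.config.prior_cpm)
        zones = self.filtered_table.zone_labels
        fig, axes = plt.subplots(1, 3, figsize=(13, 4))
        axes[0].boxplot([logc[:, i] for i in range(len(zones))], tick_labels=zones)
        axes[0].set_title("log2 CPM by zone")
        grid = np.linspace(logc.min(), logc.max(), 200)
        for i, z in enumerate(zones):
            axes[1].plot(grid, gaussian_kde(logc[:, i])(grid), label=z)
        axes[1].legend(fontsize=7)
        axes[1].set_title("density")
        # classical MDS of pairwise Euclidean distances between zones
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(logc.T))
        j = np.eye(len(zones)) - 1.0 / len(zones)
        b = -0.5 * j @ (d**2) @ j
        w, v = np.linalg.eigh(b)
        pts = v[:, ::-1][:, :2] * np.sqrt(np.maximum(w[::-1][:2], 0.0))
        axes[2].scatter(pts[:, 0], pts[:, 1])
        for i, z in enumerate(zones):
            axes[2].annotate(z, pts[i])
        axes[2].set_title("MDS")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig

    def plot_heatmap(self, path: str | Path | None = None):
        """Row-scaled CPM heatmap ordered by membership code."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        from .membership import order_for_heatmap

        order, scaled = order_for_heatmap(
            self.codes, self.normalization.cpm, self.filtered_table.zone_labels
        )
        fig, ax = plt.subplots(figsize=(4, 7))
        ax.imshow(scaled, aspect="auto", interpolation="nearest", cmap="viridis")
        ax.set_xticks(range(len(self.filtered_table.zone_labels)))
        ax.set_xticklabels(self.filtered_table.zone_labels)
        ax.set_xlabel("zone (anterior -> posterior)")
        ax.set_ylabel("transcripts (grouped by primary zone)")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: RunConfig,
    counts_path: str | Path | None = None,
    sim_config=None,
    out_dir: str | Path = ".",
    heatmap: bool = False,
    qc_cutoffs: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0),
    log=print,
) -> ZoneSpecificityResults:
    """End-to-end run writing all artifacts to ``out_dir``.

    Counts come either from ``counts_path`` or from the synthetic
    generator (``sim_config``).  Writes: counts TSV (if simulated), truth
    TSV, factors TSV, per-transcript results TSV, categories TSV, QC
    report TSV, manifest JSON, and optionally the heatmap PNG.  The run is
    a pure function of (counts file, config, seed).
    """
    from .io import read_counts
    from .simulate import simulate_zone_counts

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    checksums: dict[str, str] = {}
    truth = None
    if (counts_path is None) == (sim_config is None):
        raise ValueError("provide exactly one of counts_path or sim_config")
    if counts_path is not None:
        table = read_counts(counts_path, library_sizes=config.library_sizes)
        checksums[str(counts_path)] = _sha256(Path(counts_path))
        log(f"[read] {table.n_transcripts} transcripts x {table.n_zones} zones")
    else:
        table, truth = simulate_zone_counts(sim_config)
        write_counts(table, out / "counts.tsv")
        truth.table.to_csv(out / "truth.tsv", sep="\t", index=False)
        log(f"[simulate] {table.n_transcripts} transcripts x {table.n_zones} zones")

    results = ZoneSpecificityModel(table, config).fit()
    results.manifest.input_checksums = checksums
    m = results.manifest
    log(f"[filter] kept {m.n_kept}/{m.n_detected} at CPM >= {config.cpm_cutoff}")
    log(f"[normalize] factors {np.round(results.normalization.normalization_factors, 4)}")
    log(f"[test+score] {m.n_restricted} restricted transcripts, "
        f"{results.category_summary.n_categories} categories")

    factors = pd.DataFrame(
        {
            "zone": results.filtered_table.zone_labels,
            "normalization_factor": results.normalization.normalization_factors,
            "effective_library_size": results.normalization.effective_library_sizes,
        }
    )
    factors.to_csv(out / "factors.tsv", sep="\t", index=False, float_format="%.12g")
    write_results(results.results_frame(), out / "results.tsv")
    results.category_summary.to_frame().to_csv(
        out / "categories.tsv", sep="\t", index=False
    )
    qc = cutoff_diagnostic(table, list(qc_cutoffs))
    qc["report"].to_csv(out / "qc.tsv", sep="\t", index=False, float_format="%.12g")
    (out / "manifest.json").write_text(results.manifest.to_json() + "\n")
    if truth is not None:
        results.recovery(truth).to_csv(
            out / "recovery.tsv", sep="\t", index=False, float_format="%.12g"
        )
    if heatmap:
        results.plot_heatmap(out / "heatmap.png")
        results.plot_qc(out / "qc.png")
    return results
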