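"""Post-search TMT phospho-proteomics quantitation and significance calls.

Starting from a quantified phospho-site table and a matching protein table
(MaxQuant-style, one reporter-intensity column per TMT channel), the
pipeline

1. removes contaminant/reverse hits and sites not quantified in every
   channel,
2. optionally corrects reporter intensities for isotope impurity
   cross-channel spill (linear solve against the mixing matrix),
3. equalises channel loading by dividing each channel by its median protein
   reporter intensity,
4. forms per-replicate log2 treated/control ratios, normalised to the
   parent protein's ratio where the protein was quantified,
5. fits a normal distribution to the per-site mean log2 ratios and flags
   sites outside the fitted mean +/- 1.96 sd as significantly changing
   (nominal two-sided 5%), and
6. annotates proline-directed ([S/T]P) motifs and class-I sites
   (localisation probability > 0.75) and summarises the down-regulated set.

No multiple-testing correction is applied beyond the 1.96-sd rule; the
cutoff is deliberately an empirical-null outlier criterion, not an FDR
procedure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ConfigError

__all__ = [
    "CutoffModel",
    "DataError",
    "ExperimentDesign",
    "annotate_stp_motif",
    "compute_log_ratios",
    "correct_isotope_impurities",
    "default_design",
    "filter_valid_proteins",
    "filter_valid_sites",
    "fit_normal_cutoffs",
    "flag_significant",
    "normalize_loading",
    "run_pipeline",
    "summarize_hits",
]

logger = logging.getLogger(__name__)

#: TMT 6-plex reporter channel names.
TMT6_CHANNELS = ("126", "127", "128", "129", "130", "131")

CLASS1_THRESHOLD = 0.75
Z_CUTOFF = 1.96


class DataError(ValueError):
    """Malformed or inconsistent quantitation data."""


def intensity_column(channel: str) -> str:
    return f"intensity_{channel}"


@dataclass(frozen=True)
class ExperimentDesign:
    """Channel layout: exactly three control and three treated channels,
    paired into biological replicates 1..3."""

    channels: dict[str, tuple[str, int]]  # channel -> (group, replicate)

    def __post_init__(self) -> None:
        groups = {"control": {}, "treated": {}}
        for ch, (group, rep) in self.channels.items():
            if group not in groups:
                raise ConfigError(f"channel {ch}: group must be control/treated, got {group!r}")
            if rep in groups[group]:
                raise ConfigError(f"duplicate replicate {rep} in group {group}")
            groups[group][rep] = ch
        for group, reps in groups.items():
            if sorted(reps) != [1, 2, 3]:
                raise ConfigError(
                    f"group {group!r} must have replicates 1, 2, 3; got {sorted(reps)}"
                )
        object.__setattr__(self, "_by_group", groups)

    @property
    def replicates(self) -> tuple[int, ...]:
        return (1, 2, 3)

    def channel(self, group: str, replicate: int) -> str:
        return self._by_group[group][replicate]

    def channel_names(self) -> list[str]:
        return list(self.channels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"channel": ch, "group": g, "replicate": r} for ch, (g, r) in self.channels.items()]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExperimentDesign":
        required = {"channel", "group", "replicate"}
        missing = required - set(df.columns)
        if missing:
            raise DataError(f"design table missing column(s): {', '.join(sorted(missing))}")
        return cls(
            channels={
                str(row.channel): (str(row.group), int(row.replicate))
                for row in df.itertuples()
            }
        )


def default_design() -> ExperimentDesign:
    """TMT6 layout: 126-128 control, 129-131 treated, replicates in order."""
    channels = {}
    for i, ch in enumerate(TMT6_CHANNELS):
        group = "control" if i < 3 else "treated"
        channels[ch] = (group, i % 3 + 1)
    return ExperimentDesign(channels=channels)


def _intensity_cols(df: pd.DataFrame, channels: list[str]) -> list[str]:
    cols = [intensity_column(c) for c in channels]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataError(f"missing intensity column(s): {', '.join(missing)}")
    return cols


def filter_valid_sites(
    sites: pd.DataFrame, channels: list[str] | None = None
) -> pd.DataFrame:
    """Drop contaminant/reverse rows and rows not quantified in all channels.

    A site must carry a finite, strictly positive intensity in every used
    channel to enter ratio computation (strict completeness rule).
    """
    channels = list(channels or TMT6_CHANNELS)
    cols = _intensity_cols(sites, channels)
    n_in = len(sites)
    flagged = sites["is_contaminant"].astype(bool) | sites["is_reverse"].astype(bool)
    kept = sites.loc[~flagged]
    inten = kept[cols].to_numpy(dtype=float)
    complete = np.all(np.isfinite(inten) & (inten > 0), axis=1)
    out = kept.loc[complete].reset_index(drop=True)
    logger.info(
        "filter: %d rows in, %d flagged, %d incomplete, %d kept",
        n_in, int(flagged.sum()), int((~complete).sum()), len(out),
    )
    if len(out) == 0:
        logger.warning("filter produced an empty table")
    return out


def filter_valid_proteins(
    proteins: pd.DataFrame, channels: list[str] | None = None
) -> pd.DataFrame:
    """Protein-table analogue of :func:`filter_valid_sites`."""
    return filter_valid_sites(proteins, channels)


def make_impurity_matrix(n_channels: int = 6, spill: float = 0.05) -> np.ndarray:
    """Tridiagonal isotope-impurity mixing matrix.

    Each channel leaks ``spill`` of its signal into each adjacent channel;
    columns sum to 1.
    """
    if not 0.0 <= spill <= 0.2:
        raise ConfigError(f"spill must lie in [0, 0.2], got {spill}")
    m = np.zeros((n_channels, n_channels))
    for j in range(n_channels):
        neighbours = [i for i in (j - 1, j + 1) if 0 <= i < n_channels]
        for i in neighbours:
            m[i, j] = spill
        m[j, j] = 1.0 - spill * len(neighbours)
    return m


def correct_isotope_impurities(
    table: pd.DataFrame,
    impurity: np.ndarray,
    channels: list[str] | None = None,
) -> pd.DataFrame:
    """Undo cross-channel isotope spill by solving ``observed = M @ true``.

    Negative solutions (possible for noisy rows) are clamped to zero and
    counted in the log.
    """
    channels = list(channels or TMT6_CHANNELS)
    cols = _intensity_cols(table, channels)
    impurity = np.asarray(impurity, dtype=float)
    k = len(channels)
    if impurity.shape != (k, k):
        raise DataError(f"impurity matrix must be {k}x{k}, got {impurity.shape}")
    if np.any(impurity.sum(axis=0) > 1.0 + 1e-9):
        raise DataError("impurity matrix columns must sum to <= 1")
    if abs(np.linalg.det(impurity)) < 1e-12:
        raise DataError("impurity matrix is singular")
    observed = table[cols].to_numpy(dtype=float)
    true = np.linalg.solve(impurity, observed.T).T
    n_clamped = int(np.any(true < 0, axis=1).sum())
    if n_clamped:
        logger.warning("impurity correction clamped negatives in %d rows", n_clamped)
    out = table.copy()
    out[cols] = np.clip(true, 0.0, None)
    return out


def normalize_loading(
    sites: pd.DataFrame,
    proteins: pd.DataFrame,
    channels: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Equalise channel loading using the median protein reporter intensity.

    Every channel of both tables is divided by that channel's median protein
    intensity, so post-normalisation protein medians are identical (and
    equal to 1) across channels.  Rescaling any input channel by a constant
    therefore leaves the output exactly unchanged.
    """
    channels = list(channels or TMT6_CHANNELS)
    cols = _intensity_cols(proteins, channels)
    _intensity_cols(sites, channels)
    medians = proteins[cols].median(axis=0).to_numpy(dtype=float)
    if np.any(~np.isfinite(medians)) or np.any(medians <= 0):
        raise DataError("a channel has a non-positive median protein intensity")
    sites_out, proteins_out = sites.copy(), proteins.copy()
    for table in (sites_out, proteins_out):
        table[cols] = table[cols].to_numpy(dtype=float) / medians
    return sites_out, proteins_out


def compute_log_ratios(
    sites: pd.DataFrame,
    proteins: pd.DataFrame,
    design: ExperimentDesign,
) -> pd.DataFrame:
    """Per-site, per-replicate log2 treated/control ratios.

    For replicate ``r`` the raw ratio is ``log2(I_treated,r / I_control,r)``
    at the site; if the parent protein was quantified, the protein's own
    ratio is subtracted so that phosphorylation changes are separated from
    abundance changes.  ``mean_log2_ratio`` averages the three replicates.
    """
    prot = proteins.set_index("protein_id")
    rep_cols = [f"log2_ratio_rep{r}" for r in design.replicates]
    out = sites[
        [c for c in ("site_id", "protein_id", "position", "residue",
                     "localization_prob", "sequence_window") if c in sites.columns]
    ].copy()
    has_protein = sites["protein_id"].isin(prot.index).to_numpy()
    for r in rep_cols:
        out[r] = np.nan
    for r in design.replicates:
        ct = intensity_column(design.channel("control", r))
        tr = intensity_column(design.channel("treated", r))
        s_num = sites[tr].to_numpy(dtype=float)
        s_den = sites[ct].to_numpy(dtype=float)
        if np.any(s_den <= 0) or np.any(s_num <= 0):
            raise DataError("non-positive intensity in ratio computation; run filter_valid_sites first")
        raw = np.log2(s_num / s_den)
        prot_ratio = np.zeros(len(sites))
        matched = prot.reindex(sites["protein_id"])
        p_num = matched[tr].to_numpy(dtype=float)
        p_den = matched[ct].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            pr = np.log2(p_num / p_den)
        prot_ratio[has_protein] = pr[has_protein]
        out[f"log2_ratio_rep{r}"] = raw - prot_ratio
    out["protein_normalized"] = has_protein
    out["mean_log2_ratio"] = out[rep_cols].mean(axis=1)
    return out


@dataclass(frozen=True)
class CutoffModel:
    """Fitted normal null model and the mean +/- 1.96 sd cutoffs (log2)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean) or not math.isfinite(self.sd) or self.sd <= 0:
            raise DataError(f"invalid cutoff model: mean={self.mean}, sd={self.sd}")

    @property
    def lo(self) -> float:
        return self.mean - Z_CUTOFF * self.sd

    @property
    def hi(self) -> float:
        return self.mean + Z_CUTOFF * self.sd


def fit_normal_cutoffs(mean_log2_ratios: np.ndarray) -> CutoffModel:
    """Fit a normal distribution to the mean log2 ratios.

    Sample mean and sample standard deviation (n-1 denominator); at least
    10 finite values required, and a degenerate (zero-spread) sample raises.
    """
    x = np.asarray(mean_log2_ratios, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 10:
        raise DataError(f"need >= 10 finite log ratios to fit cutoffs, got {len(x)}")
    sd = float(np.std(x, ddof=1))
    # guard against float accumulation making a constant sample look spread
    if sd <= 1e-12 * max(1.0, float(np.max(np.abs(x)))):
        raise DataError("degenerate ratio distribution (sd = 0)")
    return CutoffModel(mean=float(np.mean(x)), sd=sd)


def flag_significant(results: pd.DataFrame, cutoffs: CutoffModel) -> pd.DataFrame:
    """Flag sites whose mean log2 ratio falls outside the fitted cutoffs.

    Boundary values are not significant (strict inequalities).
    """
    out = results.copy()
    m = out["mean_log2_ratio"].to_numpy(dtype=float)
    down = m < cutoffs.lo
    up = m > cutoffs.hi
    out["significant"] = down | up
    out["direction"] = np.where(down, "down", np.where(up, "up", "none"))
    return out


def annotate_stp_motif(window: str) -> bool:
    """True iff the central phospho-acceptor is S/T immediately followed by P.

    ``window`` is an odd-length sequence with the phospho-site at its
    centre (proline-directed, minimal Cdk-consensus definition).
    """
    if len(window) % 2 == 0:
        raise DataError(f"sequence window must have odd length, got {len(window)}")
    centre = len(window) // 2
    return window[centre] in "ST" and window[centre + 1] == "P"


def annotate_results(results: pd.DataFrame) -> pd.DataFrame:
    """Add ``is_stp_motif`` and ``is_class1`` columns."""
    out = results.copy()
    out["is_stp_motif"] = [annotate_stp_motif(w) for w in out["sequence_window"]]
    out["is_class1"] = out["localization_prob"].to_numpy(dtype=float) > CLASS1_THRESHOLD
    return out


def summarize_hits(results: pd.DataFrame, fold_threshold: float = 2.0) -> dict[str, int]:
    """Headline counts of the significance analysis.

    ``n_significant_down`` counts significant down-regulated sites whose
    mean change reaches ``fold_threshold``-fold or more;
    ``n_proteins_down`` the distinct proteins among them.  The class-I
    filter applies to the motif-level count only.
    """
    if fold_threshold <= 0:
        raise DataError("fold_threshold must be positive")
    if len(results) == 0:
        return dict(n_quantified=0, n_stp=0, n_significant_down=0,
                    n_proteins_down=0, n_class1=0)
    log2_thr = -math.log2(fold_threshold)
    down = (
        results["significant"].astype(bool)
        & (results["direction"] == "down")
        & (results["mean_log2_ratio"] <= log2_thr)
    )
    class1 = results["is_class1"].astype(bool)
    return dict(
        n_quantified=int(len(results)),
        n_stp=int((results["is_stp_motif"].astype(bool) & class1).sum()),
        n_significant_down=int(down.sum()),
        n_proteins_down=int(results.loc[down, "protein_id"].nunique()),
        n_class1=int(class1.sum()),
    )


def run_pipeline(
    sites: pd.DataFrame,
    proteins: pd.DataFrame,
    design: ExperimentDesign | None = None,
    impurity: np.ndarray | None = None,
    fold_threshold: float = 2.0,
) -> tuple[pd.DataFrame, CutoffModel, dict[str, int]]:
    """Run the full quantitation and significance procedure.

    Returns the per-site results table, the fitted cutoff model and the
    summary counts.  When no impurity matrix is supplied the identity is
    assumed (vendor correction already applied upstream).
    """
    design = design or default_design()
    channels = design.channel_names()
    sites = filter_valid_sites(sites, channels)
    proteins = filter_valid_proteins(proteins, channels)
    if impurity is not None:
        sites = correct_isotope_impurities(sites, impurity, channels)
        proteins = correct_isotope_impurities(proteins, impurity, channels)
        # correction can zero out an intensity entirely; re-apply completeness
        sites = filter_valid_sites(sites, channels)
        proteins = filter_valid_proteins(proteins, channels)
    sites, proteins = normalize_loading(sites, proteins, channels)
    ratios = compute_log_ratios(sites, proteins, design)
    cutoffs = fit_normal_cutoffs(ratios["mean_log2_ratio"].to_numpy())
    results = flag_significant(ratios, cutoffs)
    results = annotate_results(results)
    summary = summarize_hits(results, fold_threshold=fold_threshold)
    logger.info("pipeline summary: %s", summary)
    return results, cutoffs, summary
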