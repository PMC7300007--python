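"""Stable-isotope-dilution PRM quantification.

The assay spikes a heavy-isotope-labeled standard peptide (known fmol) into
a known mass of digested tissue protein.  Endogenous (light) abundance is
quantified from the light/heavy peak-area ratio after transition-level QC:

1. light transitions must have mass accuracy within ``ppm_tol`` and a heavy
   partner of the same fragment ion co-eluting within ``rt_coelute_tol``;
2. peptide peak areas are the sum of the ``top_n`` (default three) most
   abundant transitions, ranked by the heavy channel;
3. detection requires at least ``min_coeluting_transitions`` (default two)
   valid light transitions whose areas track the heavy channel (normalized
   dot-product concordance of the fragment intensity patterns, the
   spectral-contrast "dotp" measure); a peptide with exactly one valid
   transition is assigned an
   abundance of zero rather than treated as missing; with none it is
   not detected;
4. abundance (fmol/ug) = (light sum / heavy sum) * spike_fmol /
   protein_input_ug.

``PRMQuantifier`` wraps the pipeline as a scikit-learn style transformer
over a long-format transition table; the module-level functions expose the
individual steps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "QuantParams",
    "MissingStandardError",
    "filter_transitions",
    "select_top_transitions",
    "call_detection",
    "quantify_peptide",
    "quantify_peptides",
    "quantify_proteins",
    "PRMQuantifier",
]

STATUS_DETECTED = "detected"
STATUS_ZERO = "zero_assigned"
STATUS_ND = "not_detected"
_STATUS_RANK = {STATUS_DETECTED: 2, STATUS_ZERO: 1, STATUS_ND: 0}
_LABELS = frozenset({"light", "heavy"})


class MissingStandardError(ValueError):
    """Raised when a peptide has no heavy (internal standard) transitions."""


@dataclass(frozen=True)
class QuantParams:
    """QC and quantification parameters.

    ppm_tol
        Maximum absolute mass error for a light transition (inclusive).
    rt_coelute_tol
        Maximum |RT(light) - RT(heavy)| in minutes for co-elution.
    ratio_concordance_min
        Minimum normalized dot product between the light and heavy
        fragment-area patterns (checked when at least three fragments carry
        both channels; waived at two).
    min_coeluting_transitions
        Valid light transitions required for a detection call.
    top_n
        Number of most-abundant transitions summed per peptide.
    spike_fmol, protein_input_ug
        Heavy-standard spike amount and digested protein input.
    """

    ppm_tol: float = 5.0
    rt_coelute_tol: float = 0.2
    ratio_concordance_min: float = 0.8
    min_coeluting_transitions: int = 2
    top_n: int = 3
    spike_fmol: float = 50.0
    protein_input_ug: float = 100.0

    def __post_init__(self) -> None:
        if self.ppm_tol <= 0:
            raise ValueError("ppm_tol must be > 0")
        if self.rt_coelute_tol < 0:
            raise ValueError("rt_coelute_tol must be >= 0")
        if not 0.0 <= self.ratio_concordance_min <= 1.0:
            raise ValueError("ratio_concordance_min must lie in [0, 1]")
        if not self.top_n >= self.min_coeluting_transitions >= 1:
            raise ValueError("need top_n >= min_coeluting_transitions >= 1")
        if self.spike_fmol <= 0 or self.protein_input_ug <= 0:
            raise ValueError("spike_fmol and protein_input_ug must be > 0")


def _check_labels(records: pd.DataFrame) -> None:
    bad = set(records["label"].unique()) - _LABELS
    if bad:
        raise ValueError(f"unknown label value(s): {sorted(bad)}")


def filter_transitions(
    records: pd.DataFrame, params: QuantParams | None = None
) -> pd.DataFrame:
    """Apply transition-level QC to a long-format transition table.

    Light transitions are retained when |mass_error_ppm| <= ``ppm_tol``
    (boundary inclusive) AND a heavy transition of the same
    (sample, peptide, fragment) co-elutes within ``rt_coelute_tol`` minutes.
    Heavy transitions are always retained (needed for ratio and ranking).
    Row order is preserved.
    """
    params = params or QuantParams()
    _check_labels(records)
    light = records["label"] == "light"
    keep = ~light  # heavy always retained

    key = ["sample_id", "peptide_seq", "fragment_id"]
    heavy_rt = (
        records.loc[~light, key + ["rt_apex"]]
        .drop_duplicates(key)
        .rename(columns={"rt_apex": "_heavy_rt"})
    )
    merged = records.loc[light, key + ["rt_apex", "mass_error_ppm"]].merge(
        heavy_rt, on=key, how="left"
    )
    ppm_ok = merged["mass_error_ppm"].abs() <= params.ppm_tol
    coelute = (merged["rt_apex"] - merged["_heavy_rt"]).abs() <= params.rt_coelute_tol
    keep_light = (ppm_ok & coelute.fillna(False)).to_numpy()
    keep = keep.to_numpy(copy=True)
    keep[np.nonzero(light.to_numpy())[0]] = keep_light
    return records.loc[keep]


def select_top_transitions(
    records: pd.DataFrame, params: QuantParams | None = None
) -> pd.DataFrame:
    """Keep the ``top_n`` fragments of one (sample, peptide) group.

    Fragments are ranked by heavy-channel area, ties broken by fragment
    identifier (lexicographic); if fewer than ``top_n`` fragments survive
    QC, all are kept.  Raises :class:`MissingStandardError` when the group
    has no heavy transitions.
    """
    params = params or QuantParams()
    heavy = records[records["label"] == "heavy"]
    if heavy.empty:
        raise MissingStandardError(
            "no heavy transitions: internal standard not observed"
        )
    ranked = heavy.sort_values(
        ["area", "fragment_id"], ascending=[False, True], kind="mergesort"
    )
    top = list(ranked["fragment_id"].drop_duplicates().head(params.top_n))
    return records[records["fragment_id"].isin(top)]


def _pattern_concordance(light_areas: np.ndarray, heavy_areas: np.ndarray) -> float:
    """Normalized dot product of the light and heavy fragment-area patterns.

    The spectral-contrast measure used for transition-pattern QC: 1.0 when
    the endogenous fragment intensities are an exact scalar multiple of the
    standard's, degrading as individual fragment ratios become discordant.
    NaN if either pattern has zero intensity.
    """
    ln = np.linalg.norm(light_areas)
    hn = np.linalg.norm(heavy_areas)
    if ln == 0 or hn == 0:
        return float("nan")
    return float(np.dot(light_areas, heavy_areas) / (ln * hn))


def _detection_details(
    records: pd.DataFrame, params: QuantParams
) -> tuple[str, int, float, float]:
    """Detection call plus the summed areas used for quantification.

    Returns ``(status, n_valid, light_sum, heavy_sum)``.  Sums run over the
    fragments that carry a surviving light transition, with both channels
    summed over the SAME fragment set so the ratio is unbiased.
    """
    light = records[records["label"] == "light"]
    heavy = records[records["label"] == "heavy"]
    if heavy.empty:
        raise MissingStandardError(
            "no heavy transitions: internal standard not observed"
        )
    heavy_by_frag = heavy.groupby("fragment_id")["area"].sum()
    pair_frags = sorted(set(light["fragment_id"]) & set(heavy_by_frag.index))
    n_valid = len(pair_frags)

    if n_valid >= 3:
        la = light.set_index("fragment_id").loc[pair_frags, "area"].to_numpy(float)
        ha = heavy_by_frag.loc[pair_frags].to_numpy(float)
        sim = _pattern_concordance(la, ha)
        # A zero-intensity channel gives an undefined similarity; absence
        # of evidence against concordance is not treated as discordance.
        if not np.isnan(sim) and sim < params.ratio_concordance_min:
            n_valid = 0

    if n_valid >= params.min_coeluting_transitions:
        status = STATUS_DETECTED
    elif n_valid == 1:
        status = STATUS_ZERO
    else:
        status = STATUS_ND

    if n_valid == 0:
        return status, 0, 0.0, float(heavy["area"].sum())
    light_sum = float(
        light[light["fragment_id"].isin(pair_frags)]["area"].sum()
    )
    heavy_sum = float(heavy_by_frag.loc[pair_frags].sum())
    return status, n_valid, light_sum, heavy_sum


def call_detection(records: pd.DataFrame, params: QuantParams | None = None) -> str:
    """Detection status of one filtered, top-selected (sample, peptide) group.

    ``detected`` with >= ``min_coeluting_transitions`` valid, concordant
    light transitions; ``zero_assigned`` with exactly one (its abundance is
    reported as zero); ``not_detected`` with none.
    """
    params = params or QuantParams()
    status, *_ = _detection_details(records, params)
    return status


def quantify_peptide(
    light_area_sum: float,
    heavy_area_sum: float,
    params: QuantParams | None = None,
    status: str = STATUS_DETECTED,
) -> float:
    """Abundance in fmol/ug from summed light and heavy areas.

    ``(light / heavy) * spike_fmol / protein_input_ug``; a zero-assigned
    peptide is 0 regardless of areas.  Raises when the heavy sum is zero.
    """
    params = params or QuantParams()
    if status == STATUS_ZERO:
        return 0.0
    if heavy_area_sum <= 0:
        raise MissingStandardError("heavy area sum is zero: standard not observed")
    return (
        (light_area_sum / heavy_area_sum)
        * params.spike_fmol
        / params.protein_input_ug
    )


def quantify_peptides(
    records: pd.DataFrame, params: QuantParams | None = None
) -> pd.DataFrame:
    """Full per-peptide pipeline over a long-format transition table.

    Filters, selects top transitions, calls detection and quantifies each
    (sample, protein, peptide) group.  Returns one row per group with
    columns ``sample_id, protein_id, peptide_seq, light_area_sum,
    heavy_area_sum, n_valid_transitions, status, abundance_fmol_per_ug``
    (NaN when not detected).
    """
    params = params or QuantParams()
    filtered = filter_transitions(records, params)
    rows = []
    group_cols = ["sample_id", "protein_id", "peptide_seq"]
    for (sample, protein, peptide), grp in filtered.groupby(group_cols, sort=True):
        top = select_top_transitions(grp, params)
        status, n_valid, light_sum, heavy_sum = _detection_details(top, params)
        if status == STATUS_ND:
            abundance = np.nan
        else:
            abundance = quantify_peptide(light_sum, heavy_sum, params, status)
        rows.append(
            (sample, protein, peptide, light_sum, heavy_sum, n_valid, status, abundance)
        )
    return pd.DataFrame(
        rows,
        columns=group_cols
        + [
            "light_area_sum",
            "heavy_area_sum",
            "n_valid_transitions",
            "status",
            "abundance_fmol_per_ug",
        ],
    )


def quantify_proteins(
    records: pd.DataFrame,
    panel: pd.DataFrame | Iterable[str] | None = None,
    params: QuantParams | None = None,
) -> pd.DataFrame:
    """Protein-level abundances for every sample in a transition table.

    Peptide abundances from :func:`quantify_peptides` are aggregated per
    protein: the abundance is the mean over quantifiable peptides (detected
    or zero-assigned), the status is the best among peptides (detected >
    zero_assigned > not_detected).  *panel* (a DataFrame with ``protein_id``
    or an iterable of protein identifiers) fixes the reported protein set;
    panel proteins without records are emitted as ``not_detected``.

    Returns a long table ``sample_id, protein_id, fmol_per_ug, status,
    n_peptides, n_valid_transitions``.
    """
    params = params or QuantParams()
    peptides = quantify_peptides(records, params)

    if panel is None:
        panel_ids = sorted(records["protein_id"].unique())
    elif isinstance(panel, pd.DataFrame):
        panel_ids = list(pd.unique(panel["protein_id"]))
    else:
        panel_ids = list(panel)

    samples = sorted(records["sample_id"].unique())
    by_group = dict(iter(peptides.groupby(["sample_id", "protein_id"])))
    rows = []
    for sample in samples:
        for protein in panel_ids:
            grp = by_group.get((sample, protein))
            if grp is None:
                rows.append((sample, protein, np.nan, STATUS_ND, 0, 0))
                continue
            status = max(grp["status"], key=_STATUS_RANK.__getitem__)
            quant = grp["abundance_fmol_per_ug"].dropna()
            fmol = float(quant.mean()) if len(quant) else np.nan
            rows.append(
                (
                    sample,
                    protein,
                    fmol,
                    status,
                    int(len(grp)),
                    int(grp["n_valid_transitions"].max()),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "protein_id",
            "fmol_per_ug",
            "status",
            "n_peptides",
            "n_valid_transitions",
        ],
    )


class PRMQuantifier(TransformerMixin, BaseEstimator):
    """Scikit-learn style transformer: transition table -> protein abundances.

    Parameters mirror :class:`QuantParams`; ``panel`` optionally fixes the
    reported protein set.  ``transform`` accepts a long-format DataFrame
    with columns ``sample_id, protein_id, peptide_seq, fragment_id, label,
    area, mass_error_ppm, rt_apex`` and returns the long-format protein
    abundance table of :func:`quantify_proteins`.
    """

    def __init__(
        self,
        ppm_tol: float = 5.0,
        rt_coelute_tol: float = 0.2,
        ratio_concordance_min: float = 0.8,
        min_coeluting_transitions: int = 2,
        top_n: int = 3,
        spike_fmol: float = 50.0,
        protein_input_ug: float = 100.0,
        panel: Iterable[str] | None = None,
    ):
        self.ppm_tol = ppm_tol
        self.rt_coelute_tol = rt_coelute_tol
        self.ratio_concordance_min = ratio_concordance_min
        self.min_coeluting_transitions = min_coeluting_transitions
        self.top_n = top_n
        self.spike_fmol = spike_fmol
        self.protein_input_ug = protein_input_ug
        self.panel = panel

    def _params(self) -> QuantParams:
        return QuantParams(
            ppm_tol=self.ppm_tol,
            rt_coelute_tol=self.rt_coelute_tol,
            ratio_concordance_min=self.ratio_concordance_min,
            min_coeluting_transitions=self.min_coeluting_transitions,
            top_n=self.top_n,
            spike_fmol=self.spike_fmol,
            protein_input_ug=self.protein_input_ug,
        )

    def fit(self, X: pd.DataFrame, y=None) -> "PRMQuantifier":
        """Validate parameters and the input schema (stateless otherwise)."""
        self.params_ = self._params()
        missing = {
            "sample_id", "protein_id", "peptide_seq", "fragment_id",
            "label", "area", "mass_error_ppm", "rt_apex",
        } - set(X.columns)
        if missing:
            raise ValueError(f"missing transition columns: {sorted(missing)}")
        _check_labels(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "params_")
        return quantify_proteins(X, panel=self.panel, params=self.params_)

    def abundance_matrix(self, X: pd.DataFrame) -> pd.DataFrame:
        """Proteins x samples fmol/ug matrix (NaN where not detected)."""
        long = self.fit(X).transform(X)
        return long.pivot(
            index="protein_id", columns="sample_id", values="fmol_per_ug"
        )
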