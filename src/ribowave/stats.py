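"""Codon-level enrichment statistics.

The central object is the offset profile ``E[X, d]``: the mean relative
enrichment at all included positions located exactly ``d`` codons downstream
(positive ``d``) or upstream (negative ``d``) of an occurrence of codon
identity ``X``.  Offsets 0/+1/+2 are the A-, P- and E-site occupancies.

On top of the profile sit the headline analyses:

- ``wave_analysis``: per codon, the summed change in enrichment at the three
  tRNA binding sites (offsets 0..2) versus the summed change over a
  downstream window.  If downstream peaks are transient waves shed by
  continued elongation under switched rates, the two sum to zero and the
  regression of wave area on binding-site change has slope -1.
- ``corrected aggregate enrichment`` (CAE): binding-site enrichment plus the
  net downstream wave area — an estimate of a codon's total decode-time
  signature before the perturbation.
- ``compute_tai``: the tRNA adaptation index from genomic tRNA copy numbers
  with wobble-pairing penalties, and rank correlations of occupancy
  statistics against 1/tAI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import ParameterError
from .footprints import RelativeEnrichment
from .genetic_code import (
    CODON_INDEX,
    N_SENSE,
    SENSE_CODONS,
    reverse_complement,
)
from .sequences import CodingSequenceSet

#: documented downstream-window presets (codon offsets, inclusive)
WINDOW_PRESETS = {"matched-pair": (6, 65), "aggregate": (7, 90)}


# ---------------------------------------------------------------------------
# offset profiles


@dataclass
class OffsetProfile:
    """``E[X, d]`` matrix: 61 codons x offsets, plus contributing counts.

    ``sd`` (when available) is the sample standard deviation of the
    enrichment values within each stratum; ``stderr()`` derives the standard
    error of each mean, the natural scale for flatness z-tests.
    """

    E: pd.DataFrame  # index: codon, columns: int offsets
    n: pd.DataFrame
    sd: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if list(self.E.index) != list(SENSE_CODONS):
            raise ParameterError("profile must be indexed by the 61 sense codons")

    @property
    def offsets(self) -> np.ndarray:
        return np.asarray(self.E.columns, dtype=int)

    def covers(self, offsets) -> bool:
        return set(int(d) for d in offsets) <= set(self.E.columns)

    def stderr(self) -> pd.DataFrame:
        if self.sd is None:
            raise ParameterError("profile carries no within-stratum variances")
        return self.sd / np.sqrt(self.n.clip(lower=1))

    def to_tsv(self, path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(header)
            self.E.rename_axis("codon").to_csv(fh, sep="\t")


def unit_profile(offsets) -> OffsetProfile:
    """Flat baseline profile: ``E == 1`` everywhere (no-perturbation expectation)."""
    offsets = sorted(int(d) for d in offsets)
    E = pd.DataFrame(1.0, index=list(SENSE_CODONS), columns=offsets)
    n = pd.DataFrame(1, index=list(SENSE_CODONS), columns=offsets)
    return OffsetProfile(E, n)


def offset_profile(
    enrichment: RelativeEnrichment,
    cds: CodingSequenceSet,
    offsets=range(-90, 91),
) -> OffsetProfile:
    """Average relative enrichment at each offset around each codon identity.

    A position ``p`` contributes to ``E[X, d]`` when the codon at ``p - d``
    is an occurrence of ``X`` and *both* ``p`` and ``p - d`` are inside the
    gene's inclusion mask.
    """
    offsets = sorted(int(d) for d in offsets)
    if not offsets:
        raise ParameterError("empty offset range")
    pad = max(abs(offsets[0]), abs(offsets[-1])) + 1

    # concatenate genes with wide sentinel gaps so shifts never cross genes
    e_parts: list[np.ndarray] = []
    c_parts: list[np.ndarray] = []
    gap_e = np.full(pad, np.nan)
    gap_c = np.full(pad, -1, dtype=np.int64)
    for gene_id, e in enrichment.values.items():
        rec = cds[gene_id]
        cidx = rec.codon_indices()
        anchors = np.where(np.isfinite(e), cidx, -1)  # only included positions anchor
        e_parts.extend([gap_e, e])
        c_parts.extend([gap_c, anchors])
    e_parts.append(gap_e)
    c_parts.append(gap_c)
    e_flat = np.concatenate(e_parts)
    c_flat = np.concatenate(c_parts)

    sums = np.zeros((N_SENSE, len(offsets)))
    sq_sums = np.zeros((N_SENSE, len(offsets)))
    counts = np.zeros((N_SENSE, len(offsets)), dtype=np.int64)
    for j, d in enumerate(offsets):
        if d >= 0:
            vals = e_flat[d:] if d else e_flat
            anch = c_flat[: e_flat.size - d] if d else c_flat
        else:
            vals = e_flat[:d]
            anch = c_flat[-d:]
        ok = (anch >= 0) & np.isfinite(vals)
        a, v = anch[ok], vals[ok]
        sums[:, j] = np.bincount(a, weights=v, minlength=N_SENSE)
        sq_sums[:, j] = np.bincount(a, weights=v * v, minlength=N_SENSE)
        counts[:, j] = np.bincount(a, minlength=N_SENSE)

    with np.errstate(invalid="ignore", divide="ignore"):
        E = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        var = np.where(
            counts > 1,
            (sq_sums - np.maximum(counts, 1) * E**2) / np.maximum(counts - 1, 1),
            np.nan,
        )
    idx = list(SENSE_CODONS)
    return OffsetProfile(
        pd.DataFrame(E, index=idx, columns=offsets),
        pd.DataFrame(counts, index=idx, columns=offsets),
        pd.DataFrame(np.sqrt(np.clip(var, 0.0, None)), index=idx, columns=offsets),
    )


def site_occupancies(profile: OffsetProfile) -> pd.DataFrame:
    """Extract A/P/E-site occupancies (offsets 0, +1, +2)."""
    if not profile.covers((0, 1, 2)):
        raise ParameterError("profile does not cover offsets 0, 1, 2")
    out = profile.E[[0, 1, 2]].copy()
    out.columns = ["A", "P", "E"]
    return out


# ---------------------------------------------------------------------------
# tRNA adaptation index


#: wobble penalties in the spirit of the classic tAI parameterization;
#: pair labels are anticodon-position-34 base : codon-position-3 base,
#: with genomically encoded A34 read as inosine (I).
DEFAULT_WOBBLE_PENALTIES = {
    "WC": 0.0,
    "I:U": 0.0,
    "I:C": 0.28,
    "I:A": 0.9999,
    "G:U": 0.41,
    "U:G": 0.68,
}

# codon third base -> [(anticodon first base, pair label), ...];
# the first entry is the Watson-Crick (or I:U) cognate, the second the wobble.
_THIRD_BASE_DECODING = {
    "T": [("A", "I:U"), ("G", "G:U")],
    "C": [("G", "WC"), ("A", "I:C")],
    "A": [("T", "WC"), ("A", "I:A")],
    "G": [("C", "WC"), ("T", "U:G")],
}


@dataclass
class TAITable:
    """Per-codon tAI values plus the inputs they were derived from."""

    tai: pd.Series
    weights: pd.Series  # un-normalized weighted availabilities W_X
    tgcn: dict = field(default_factory=dict)
    penalties: dict = field(default_factory=dict)

    def inverse(self) -> pd.Series:
        return 1.0 / self.tai


def decoding_anticodons(codon: str) -> list[tuple[str, str]]:
    """Anticodons that can decode ``codon`` with their pairing labels.

    The anticodon is written 5'->3'; its bases 2-3 Watson-Crick pair the
    codon's bases 2-1, and its first (position 34) base pairs the codon's
    third base either canonically or through one wobble interaction.
    """
    stem = reverse_complement(codon[:2])  # anticodon positions 35-36
    return [
        (first + stem, label) for first, label in _THIRD_BASE_DECODING[codon[2]]
    ]


def compute_tai(
    tgcn: dict[str, float] | pd.Series,
    s_weights: dict[str, float] | None = None,
    codons=SENSE_CODONS,
) -> TAITable:
    """tRNA adaptation index from gene copy numbers and wobble penalties.

    ``W_X = sum over decoding anticodons a of (1 - s(pairing)) * tGCN_a``,
    normalized so the best codon has tAI exactly 1.  A codon with no decoding
    anticodon of positive weight is an error.
    """
    s = dict(DEFAULT_WOBBLE_PENALTIES if s_weights is None else s_weights)
    for label, val in s.items():
        if not 0.0 <= val <= 1.0:
            raise ParameterError(f"penalty {label}={val} outside [0, 1]")
    gcn = pd.Series(tgcn, dtype=float)
    if (gcn < 0).any():
        raise ParameterError("tRNA gene copy numbers must be >= 0")
    W = {}
    for codon in codons:
        w = 0.0
        for anticodon, label in decoding_anticodons(codon):
            if label not in s:
                raise ParameterError(f"no penalty declared for pairing {label}")
            w += (1.0 - s[label]) * float(gcn.get(anticodon, 0.0))
        W[codon] = w
    weights = pd.Series(W, name="W")
    if (weights <= 0).any():
        dead = list(weights.index[weights <= 0])[:5]
        raise ParameterError(f"codons with no decoding anticodon of positive weight: {dead}")
    tai = weights / weights.max()
    tai.name = "tai"
    return TAITable(tai=tai, weights=weights, tgcn=dict(gcn), penalties=s)


def spearman_vs_inverse_tai(values: pd.Series, tai: TAITable) -> tuple[float, float]:
    """Rank correlation of a per-codon statistic with 1/tAI.

    Returns ``(rho, one_tailed_p)`` with the one-tailed p-value for a
    *positive* association (slower decoding of low-tAI codons).
    """
    v = pd.Series(values, dtype=float)
    inv = tai.inverse()
    common = v.index.intersection(inv.index)
    v = v.loc[common]
    inv = inv.loc[common]
    ok = np.isfinite(v.to_numpy()) & np.isfinite(inv.to_numpy())
    if ok.sum() < 4:
        raise ParameterError("need >= 4 codons with finite values")
    if v[ok].nunique() == 1 or inv[ok].nunique() == 1:
        raise ParameterError("constant input: rank correlation undefined")
    res = sps.spearmanr(v[ok], inv[ok], alternative="greater")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# cross-experiment comparison


def experiment_correlation_matrix(
    occupancy_tables: dict[str, pd.DataFrame], site: str = "A"
) -> pd.DataFrame:
    """Pearson correlation of per-codon occupancies between experiments."""
    if site not in ("A", "P", "E"):
        raise ParameterError("site must be one of A, P, E")
    if len(occupancy_tables) < 2:
        raise ParameterError("need at least 2 experiments")
    cols = {}
    codon_index = None
    for label, table in occupancy_tables.items():
        col = table[site]
        if codon_index is None:
            codon_index = col.index
        elif not col.index.equals(codon_index):
            raise ParameterError(f"experiment {label!r}: codon set mismatch")
        if col.nunique() == 1:
            raise ParameterError(f"experiment {label!r}: constant occupancies")
        cols[label] = col.to_numpy(dtype=float)
    labels = list(cols)
    mat = np.corrcoef(np.vstack([cols[k] for k in labels]))
    return pd.DataFrame(mat, index=labels, columns=labels)


@dataclass
class UPGMAResult:
    labels: list[str]
    linkage: np.ndarray
    newick: str

    def top_split(self) -> tuple[set[str], set[str]]:
        """Leaf labels of the two clades under the root."""
        tree = hierarchy.to_tree(self.linkage)
        left = tree.get_left().pre_order(lambda leaf: self.labels[leaf.id])
        right = tree.get_right().pre_order(lambda leaf: self.labels[leaf.id])
        return set(left), set(right)


def upgma_cluster(matrix: pd.DataFrame) -> UPGMAResult:
    """Average-linkage (UPGMA) clustering on Euclidean distances between rows.

    Rows are sorted lexicographically by label first so that distance ties
    resolve identically across platforms.  The dendrogram is serialized as a
    rooted newick string with UPGMA branch lengths (half the merge height).
    """
    if matrix.shape[0] != matrix.shape[1]:
        raise ParameterError("correlation matrix must be square")
    order = sorted(matrix.index)
    m = matrix.loc[order, order]
    dist = pdist(m.to_numpy(dtype=float), metric="euclidean")
    Z = hierarchy.linkage(dist, method="average")
    tree = hierarchy.to_tree(Z)

    def to_newick(node, parent_height: float) -> str:
        height = 0.0 if node.is_leaf() else node.dist / 2.0
        length = parent_height - height
        if node.is_leaf():
            return f"{order[node.id]}:{length:.6g}"
        left = to_newick(node.get_left(), height)
        right = to_newick(node.get_right(), height)
        return f"({left},{right}):{length:.6g}"

    root_height = tree.dist / 2.0
    newick = f"({to_newick(tree.get_left(), root_height)},{to_newick(tree.get_right(), root_height)});"
    return UPGMAResult(labels=list(order), linkage=Z, newick=newick)


# ---------------------------------------------------------------------------
# downstream-wave conservation analysis


@dataclass
class WaveAnalysisResult:
    """Per-codon binding-site changes, wave areas, CAE, and the regression."""

    per_codon: pd.DataFrame
    window: tuple[int, int]
    slope: float
    intercept: float
    r_squared: float
    regression_defined: bool


def wave_analysis(
    profile_test: OffsetProfile,
    profile_ref: OffsetProfile | None = None,
    window: tuple[int, int] = WINDOW_PRESETS["aggregate"],
) -> WaveAnalysisResult:
    """Compare binding-site enrichment changes against downstream wave areas.

    ``delta_binding`` sums ``E_test - E_ref`` over offsets {0, 1, 2};
    ``wave_area`` sums it over the downstream window; ``corrected_aggregate``
    is ``sum of E_test over {0,1,2} + wave_area``.  ``profile_ref=None``
    uses the flat unit baseline (single-experiment mode).  The regression is
    OLS of wave area on binding-site change across codons, with intercept.
    """
    d_lo, d_hi = int(window[0]), int(window[1])
    if d_lo < 3:
        raise ParameterError("window must start at offset >= 3 (clear of binding sites)")
    if d_hi < d_lo:
        raise ParameterError("window upper bound below lower bound")
    down = list(range(d_lo, d_hi + 1))
    needed = [0, 1, 2] + down
    if profile_ref is None:
        profile_ref = unit_profile(needed)
    for prof, name in ((profile_test, "test"), (profile_ref, "ref")):
        if not prof.covers(needed):
            raise ParameterError(f"{name} profile does not cover offsets 0..2 and the window")

    diff = profile_test.E[needed] - profile_ref.E[needed]
    delta_binding = diff[[0, 1, 2]].sum(axis=1, min_count=3)
    wave_area = diff[down].sum(axis=1, min_count=len(down))
    cae = profile_test.E[[0, 1, 2]].sum(axis=1, min_count=3) + wave_area

    centers, heights, widths = {}, {}, {}
    for codon in SENSE_CODONS:
        excess = (
            profile_test.E.loc[codon, down].to_numpy(dtype=float)
            - profile_ref.E.loc[codon, down].to_numpy(dtype=float)
        )
        pk = _peak_from_excess(np.asarray(down), excess)
        centers[codon], heights[codon], widths[codon] = pk

    per_codon = pd.DataFrame(
        {
            "delta_binding": delta_binding,
            "wave_area": wave_area,
            "corrected_aggregate": cae,
            "peak_center": pd.Series(centers),
            "peak_height": pd.Series(heights),
            "peak_width": pd.Series(widths),
        }
    ).loc[list(SENSE_CODONS)]

    ok = np.isfinite(per_codon["delta_binding"]) & np.isfinite(per_codon["wave_area"])
    x = per_codon.loc[ok, "delta_binding"].to_numpy()
    y = per_codon.loc[ok, "wave_area"].to_numpy()
    if ok.sum() >= 3 and np.ptp(x) > 0 and np.ptp(y) > 0:
        fit = sps.linregress(x, y)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
        defined = True
    else:
        slope = intercept = r2 = float("nan")
        defined = False
    return WaveAnalysisResult(per_codon, (d_lo, d_hi), slope, intercept, r2, defined)


def _peak_from_excess(offsets: np.ndarray, excess: np.ndarray):
    pos = np.clip(excess, 0.0, None)
    pos = np.where(np.isfinite(pos), pos, 0.0)
    total = pos.sum()
    if total <= 0:
        return float("nan"), float("nan"), float("nan")
    center = float(np.dot(offsets, pos) / total)
    height = float(np.nanmax(excess))
    width = float(np.sqrt(np.dot((offsets - center) ** 2, pos) / total))
    return center, height, width


def peak_center(
    profile: OffsetProfile,
    codon: str,
    window: tuple[int, int],
    baseline: float = 1.0,
):
    """Centroid/height/width of the positive excess over ``baseline``.

    Returns ``(center, height, width)``; all NaN when there is no positive
    excess in the window (flagged undefined).
    """
    if codon not in CODON_INDEX:
        raise ParameterError(f"{codon!r} is not a sense codon")
    d_lo, d_hi = int(window[0]), int(window[1])
    down = list(range(d_lo, d_hi + 1))
    if not profile.covers(down):
        raise ParameterError("window outside profile offsets")
    excess = profile.E.loc[codon, down].to_numpy(dtype=float) - baseline
    return _peak_from_excess(np.asarray(down), excess)
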