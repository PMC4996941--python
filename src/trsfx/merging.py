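"""Monte-Carlo merging of serial snapshot intensities.

Implements the reduction chain used for serial snapshot data: resolution of
the merohedral indexing ambiguity by iterative correlation with a merged
reference, iterative per-crystal scaling (linear scale + relative B) with
rejection rules (|relative B| > 100 Å², saturated observations, per-crystal
conservative resolution limits extended by 0.3 nm⁻¹), unweighted
Monte-Carlo merging, and the half-data-set quality statistics
R_split = (1/√2)·Σ|I_even − I_odd| / (½·Σ(I_even + I_odd)),
CC_1/2 (Pearson) and CC* = √(2·CC_1/2 / (1 + CC_1/2)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reflections import AmplitudeSet
from .simulate import ObservationList
from .symmetry import apply_index_op, reduce_to_asu
from .toy import unique_asu_hkl

__all__ = [
    "CrystalScale",
    "MergedSet",
    "MergedHalves",
    "MergeStats",
    "resolve_indexing_ambiguity",
    "scale_crystals",
    "merge_monte_carlo",
    "split_halves",
    "compute_rsplit",
    "compute_cc",
    "shell_statistics",
    "equal_volume_edges",
]

RES_EXTEND_NM_INV_DEFAULT = 0.3  # extension of per-crystal limits, nm⁻¹ in 1/d
B_REJECT_DEFAULT = 100.0         # Å², reject crystals with |relative B| above


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _group_by_hkl(hkl: np.ndarray):
    """Unique canonical indices and the inverse mapping."""
    uniq, inverse = np.unique(hkl, axis=0, return_inverse=True)
    return uniq, inverse.ravel()


def _mean_by_group(inverse: np.ndarray, values: np.ndarray, n_groups: int):
    sums = np.bincount(inverse, weights=values, minlength=n_groups)
    counts = np.bincount(inverse, minlength=n_groups)
    with np.errstate(invalid="ignore"):
        return sums / counts, counts


def _reference_dict(obs: ObservationList) -> dict:
    keep = ~obs.saturated
    uniq, inv = _group_by_hkl(obs.hkl[keep])
    means, _ = _mean_by_group(inv, obs.intensity[keep], len(uniq))
    return {tuple(h): m for h, m in zip(uniq, means)}


# ---------------------------------------------------------------------------
# indexing-ambiguity resolution
# ---------------------------------------------------------------------------

def resolve_indexing_ambiguity(
    obs: ObservationList,
    seed: int = 0,
    max_iter: int = 30,
    min_common: int = 3,
    reference: dict | None = None,
) -> tuple[ObservationList, np.ndarray, dict]:
    """Assign each crystal to one of the two merohedral indexing settings.

    Iterative greedy algorithm: starting from random labels, each crystal is
    correlated with the current merged reference under both indexings and
    takes the better one, until no label changes.  The two-cluster solution
    is defined only up to a global flip; passing ``reference`` (a dict of
    hkl tuple -> intensity, e.g. from a model or an already-oriented data
    set) pins the global orientation by a final correlation check against
    it.  Crystals sharing fewer than ``min_common`` reflections with the
    reference under either labeling are left unassigned and flagged.

    Returns the relabeled observations, the per-crystal flip decision
    (indexed by crystal id) and a diagnostics dict with ``n_iter``,
    ``changed_last`` and ``unassigned`` crystal ids.
    """
    sg = obs.spacegroup
    amb = sg.ambiguity_op
    ids = obs.crystal_ids
    n_crystals = ids.max() + 1 if len(ids) else 0
    flips = np.zeros(n_crystals, dtype=bool)
    if amb is None or len(ids) <= 1:
        return obs, flips, {"n_iter": 0, "unassigned": [], "changed_last": 0}

    # per-crystal views and precomputed flipped indices
    per_crystal = {}
    for c in ids:
        mask = (obs.crystal_id == c) & ~obs.saturated
        hkl = obs.hkl[mask]
        per_crystal[c] = (
            hkl,
            reduce_to_asu(apply_index_op(hkl, amb), sg),
            obs.intensity[mask],
        )

    rng = np.random.default_rng(seed)
    flips[ids] = rng.random(len(ids)) < 0.5
    unassigned: set = set()

    def corr(hkl, inten, ref) -> float:
        pairs = [(inten[i], ref[tuple(h)]) for i, h in enumerate(hkl) if tuple(h) in ref]
        if len(pairs) < min_common:
            return np.nan
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        if a.std() == 0 or b.std() == 0:
            return np.nan
        return float(np.corrcoef(a, b)[0, 1])

    n_changed = 0
    for it in range(1, max_iter + 1):
        ref = _reference_dict(_apply_flips(obs, flips))
        n_changed = 0
        unassigned = set()
        for c in ids:
            hkl, hkl_f, inten = per_crystal[c]
            c_orig = corr(hkl, inten, ref)
            c_flip = corr(hkl_f, inten, ref)
            if np.isnan(c_orig) and np.isnan(c_flip):
                unassigned.add(int(c))
                continue
            if np.isnan(c_flip):
                new = False
            elif np.isnan(c_orig):
                new = True
            elif c_flip > c_orig:
                new = True
            elif c_orig > c_flip:
                new = False
            else:  # tie: keep current label
                new = flips[c]
            if new != flips[c]:
                flips[c] = new
                n_changed += 1
        if n_changed == 0:
            break

    if reference is not None:
        # pin the global orientation: compare the two global labelings of the
        # merged result against the external reference
        merged_now = _reference_dict(_apply_flips(obs, flips))
        merged_flip = _reference_dict(_apply_flips(obs, ~flips))

        def global_corr(merged: dict) -> float:
            pairs = [(v, reference[h]) for h, v in merged.items() if h in reference]
            if len(pairs) < min_common:
                return np.nan
            a = np.array([p[0] for p in pairs])
            b = np.array([p[1] for p in pairs])
            if a.std() == 0 or b.std() == 0:
                return np.nan
            return float(np.corrcoef(a, b)[0, 1])

        c_now, c_flip = global_corr(merged_now), global_corr(merged_flip)
        if np.isfinite(c_flip) and (not np.isfinite(c_now) or c_flip > c_now):
            flips = ~flips
    return (
        _apply_flips(obs, flips),
        flips,
        {"n_iter": it, "changed_last": n_changed, "unassigned": sorted(unassigned)},
    )


def _apply_flips(obs: ObservationList, flips: np.ndarray) -> ObservationList:
    amb = obs.spacegroup.ambiguity_op
    if amb is None or not flips.any():
        return obs
    hkl = obs.hkl.copy()
    mask = flips[obs.crystal_id]
    hkl[mask] = reduce_to_asu(apply_index_op(hkl[mask], amb), obs.spacegroup)
    return ObservationList(
        hkl=hkl, intensity=obs.intensity, sigma=obs.sigma,
        crystal_id=obs.crystal_id, saturated=obs.saturated,
        cell=obs.cell, spacegroup=obs.spacegroup,
    )


# ---------------------------------------------------------------------------
# scaling with rejection rules
# ---------------------------------------------------------------------------

@dataclass
class CrystalScale:
    """Fitted per-crystal scaling model and rejection status."""

    crystal_id: int
    scale: float          # linear scale k_c on intensities
    rel_b: float          # relative B_c, Å²
    resolution_limit: float | None = None  # Å (conservative per-crystal limit)
    rejected: bool = False
    reason: str = ""

    def __post_init__(self) -> None:
        if not self.rejected and self.scale <= 0:
            raise ValueError("scale must be positive for kept crystals")


def scale_crystals(
    obs: ObservationList,
    n_cycles: int = 3,
    b_reject: float = B_REJECT_DEFAULT,
    res_extend_nm_inv: float = RES_EXTEND_NM_INV_DEFAULT,
    n_res_shells: int = 10,
    apply_res_limit: bool = True,
) -> tuple[ObservationList, list]:
    """Iteratively scale crystals against the merged reference.

    Per cycle, all (unsaturated) observations are merged into a reference and
    each crystal's log intensity ratio is fitted linearly against s² = 1/d²:
    ln(I_c / I_ref) = ln k_c − B_c s²/2.  Scaled intensities I / (k_c
    exp(−B_c s²/2)) feed the next cycle's reference.  After the final cycle,
    crystals with |B_c| > ``b_reject`` are rejected, and each kept crystal's
    reflections are truncated at its conservative resolution limit (weakest
    of ``n_res_shells`` equal-volume shells with mean I/σ ≥ 1) extended by
    ``res_extend_nm_inv`` in 1/d.  Saturated observations never enter any
    fit or reference.
    """
    ids = obs.crystal_ids
    if len(ids) == 0:
        raise ValueError("no crystals to scale")
    s2 = 1.0 / obs.d**2
    k_tot = {int(c): 1.0 for c in ids}
    b_tot = {int(c): 0.0 for c in ids}
    intensity = obs.intensity.copy()
    sigma = obs.sigma.copy()

    crystal_masks = {int(c): obs.crystal_id == c for c in ids}
    for _ in range(n_cycles):
        work = ObservationList(
            hkl=obs.hkl, intensity=intensity, sigma=sigma,
            crystal_id=obs.crystal_id, saturated=obs.saturated,
            cell=obs.cell, spacegroup=obs.spacegroup,
        )
        ref = _reference_dict(work)
        for c in ids:
            mask = crystal_masks[int(c)] & ~obs.saturated
            hkl_c = obs.hkl[mask]
            i_c = intensity[mask]
            s2_c = s2[mask]
            ref_i = np.array([ref.get(tuple(h), np.nan) for h in hkl_c])
            ok = np.isfinite(ref_i) & (ref_i > 0) & (i_c > 0)
            if ok.sum() < 2:
                continue
            y = np.log(i_c[ok] / ref_i[ok])
            x = s2_c[ok]
            if np.ptp(x) < 1e-12:
                slope, intercept = 0.0, float(np.mean(y))
            else:
                slope, intercept = np.polyfit(x, y, 1)
            k_c = float(np.exp(intercept))
            b_c = float(-2.0 * slope)
            corr = k_c * np.exp(-b_c * s2[crystal_masks[int(c)]] / 2.0)
            intensity[crystal_masks[int(c)]] /= corr
            sigma[crystal_masks[int(c)]] /= corr
            k_tot[int(c)] *= k_c
            b_tot[int(c)] += b_c

    scales: list = []
    keep_mask = np.zeros(len(obs), dtype=bool)
    last_reason = ""
    d_all = obs.d
    inv_d = 1.0 / d_all
    extend = res_extend_nm_inv / 10.0  # nm⁻¹ → Å⁻¹
    for c in ids:
        cid = int(c)
        cs = CrystalScale(crystal_id=cid, scale=k_tot[cid], rel_b=b_tot[cid])
        if abs(cs.rel_b) > b_reject:
            cs.rejected, cs.reason = True, "relative-B"
            last_reason = "relative-B"
            scales.append(cs)
            continue
        mask = crystal_masks[cid] & ~obs.saturated
        if apply_res_limit:
            limit_inv_d = _conservative_limit(
                inv_d[mask], intensity[mask], sigma[mask], n_res_shells
            )
            if limit_inv_d is None:
                cs.rejected, cs.reason = True, "resolution"
                last_reason = "resolution"
                scales.append(cs)
                continue
            cs.resolution_limit = 1.0 / limit_inv_d
            keep_mask |= crystal_masks[cid] & (inv_d <= limit_inv_d + extend)
        else:
            keep_mask |= crystal_masks[cid]
        scales.append(cs)
    if not keep_mask.any():
        raise ValueError(
            f"all crystals rejected (last rejection rule: {last_reason or 'resolution'})"
        )
    scaled = ObservationList(
        hkl=obs.hkl[keep_mask], intensity=intensity[keep_mask],
        sigma=sigma[keep_mask], crystal_id=obs.crystal_id[keep_mask],
        saturated=obs.saturated[keep_mask], cell=obs.cell,
        spacegroup=obs.spacegroup,
    )
    return scaled, scales


def _conservative_limit(inv_d, intensity, sigma, n_shells) -> float | None:
    """Highest-resolution equal-volume shell edge with mean I/σ ≥ 1 (in 1/d)."""
    if len(inv_d) == 0:
        return None
    lo3, hi3 = inv_d.min() ** 3, inv_d.max() ** 3
    if hi3 - lo3 < 1e-12:
        ios = np.mean(intensity / sigma)
        return float(inv_d.max()) if ios >= 1.0 else None
    edges = np.cbrt(np.linspace(lo3, hi3, n_shells + 1))
    limit = None
    for i in range(n_shells):
        sel = (inv_d >= edges[i] - 1e-12) & (inv_d <= edges[i + 1] + 1e-12)
        if not sel.any():
            continue
        if np.mean(intensity[sel] / sigma[sel]) >= 1.0:
            limit = float(edges[i + 1])
    return limit


# ---------------------------------------------------------------------------
# Monte-Carlo merging
# ---------------------------------------------------------------------------

@dataclass
class MergedSet:
    """Merged intensities per ASU-unique reflection."""

    hkl: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    multiplicity: np.ndarray
    cell: object
    spacegroup: object
    d_min: float
    completeness: float = np.nan       # %
    mean_multiplicity: float = np.nan
    d: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.d is None:
            self.d = self.cell.d_spacing(self.hkl)

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def resolution_range(self) -> tuple:
        return float(self.d.max()), float(self.d.min())

    def index_map(self) -> dict:
        return {tuple(h): i for i, h in enumerate(self.hkl)}

    def to_amplitude_set(self, label: str) -> AmplitudeSet:
        """|F| = sqrt(max(I, 0)); σ_F by first-order propagation."""
        amp = np.sqrt(np.clip(self.intensity, 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            sig = np.where(amp > 0, self.sigma / (2.0 * np.maximum(amp, 1e-12)),
                           np.sqrt(np.abs(self.sigma)))
        return AmplitudeSet(hkl=self.hkl.copy(), amp=amp, sigma=sig,
                            cell=self.cell, spacegroup=self.spacegroup, label=label)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "h": self.hkl[:, 0], "k": self.hkl[:, 1], "l": self.hkl[:, 2],
                "I": self.intensity, "sigma": self.sigma,
                "multiplicity": self.multiplicity,
            }
        ).to_csv(path, index=False)


def merge_monte_carlo(obs: ObservationList, d_min: float | None = None) -> MergedSet:
    """Unweighted mean of scaled snapshot intensities per unique reflection.

    Saturated observations are excluded.  The merged sigma is SD/√n for
    multiplicity ≥ 2 and the propagated single-observation sigma otherwise.
    Completeness is measured against the full ASU sphere to ``d_min``
    (default: the highest resolution among the kept observations).
    """
    keep = ~obs.saturated
    if not keep.any():
        raise ValueError("no unsaturated observations to merge")
    hkl = obs.hkl[keep]
    inten = obs.intensity[keep]
    sig = obs.sigma[keep]
    uniq, inv = _group_by_hkl(hkl)
    n = len(uniq)
    mean, counts = _mean_by_group(inv, inten, n)
    # SD/sqrt(n) via per-group sum of squares
    sumsq = np.bincount(inv, weights=inten**2, minlength=n)
    var = np.zeros(n)
    multi = counts >= 2
    var[multi] = (sumsq[multi] - counts[multi] * mean[multi] ** 2) / (counts[multi] - 1)
    var = np.clip(var, 0.0, None)
    merged_sigma = np.where(multi, np.sqrt(var / np.maximum(counts, 1)), 0.0)
    # single-observation: propagate the observation sigma
    single_sigma = np.zeros(n)
    order = np.argsort(inv, kind="stable")
    first_idx = np.searchsorted(inv[order], np.arange(n))
    single_sigma[:] = sig[order][first_idx]
    merged_sigma = np.where(multi, merged_sigma, single_sigma)
    merged_sigma = np.maximum(merged_sigma, 1e-12)

    d = obs.cell.d_spacing(uniq)
    dm = float(d.min()) if d_min is None else float(d_min)
    possible = unique_asu_hkl(obs.cell, obs.spacegroup, dm)
    n_obs_in = int(np.sum(d >= dm - 1e-9))
    completeness = 100.0 * n_obs_in / len(possible)
    return MergedSet(
        hkl=uniq, intensity=mean, sigma=merged_sigma,
        multiplicity=counts.astype(float), cell=obs.cell,
        spacegroup=obs.spacegroup, d_min=dm,
        completeness=completeness, mean_multiplicity=float(counts.mean()), d=d,
    )


@dataclass
class MergedHalves:
    """Even/odd-crystal half data sets of one observation list."""

    even: MergedSet
    odd: MergedSet

    def common(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(hkl, I_even, I_odd) on the common index subset."""
        map_o = self.odd.index_map()
        rows = [(h, i) for i, h in enumerate(map(tuple, self.even.hkl)) if h in map_o]
        if not rows:
            return np.empty((0, 3), int), np.empty(0), np.empty(0)
        hkl = np.array([r[0] for r in rows], dtype=int)
        ie = self.even.intensity[[r[1] for r in rows]]
        io = self.odd.intensity[[map_o[r[0]] for r in rows]]
        return hkl, ie, io


def split_halves(obs: ObservationList, d_min: float | None = None) -> MergedHalves:
    """Merge even- and odd-indexed crystals separately (by crystal parity)."""
    ids = obs.crystal_ids
    parity = {int(c): (rank % 2 == 0) for rank, c in enumerate(ids)}
    even_mask = np.array([parity[int(c)] for c in obs.crystal_id])
    even = merge_monte_carlo(obs.subset(even_mask), d_min=d_min)
    odd = merge_monte_carlo(obs.subset(~even_mask), d_min=d_min)
    return MergedHalves(even=even, odd=odd)


# ---------------------------------------------------------------------------
# quality statistics
# ---------------------------------------------------------------------------

def compute_rsplit(halves: MergedHalves) -> float:
    """R_split = (1/√2)·Σ|I_even − I_odd| / (½·Σ(I_even + I_odd))."""
    _, ie, io = halves.common()
    if len(ie) == 0:
        raise ValueError("no common reflections between half data sets")
    denom = 0.5 * np.sum(ie + io)
    if denom == 0:
        raise ValueError("zero denominator in R_split")
    return float(np.sum(np.abs(ie - io)) / (np.sqrt(2.0) * denom))


def compute_cc(halves_or_pair) -> tuple[float, float]:
    """(CC_1/2, CC*) of half-set intensities.

    CC* = √(2·CC_1/2/(1+CC_1/2)); reported as NaN (undefined) when
    CC_1/2 ≤ 0 or when a half set is constant.
    """
    if isinstance(halves_or_pair, MergedHalves):
        _, ie, io = halves_or_pair.common()
    else:
        ie, io = (np.asarray(v, float) for v in halves_or_pair)
    if len(ie) < 3:
        raise ValueError("need at least 3 common reflections for CC_1/2")
    if ie.std() == 0 or io.std() == 0:
        return float("nan"), float("nan")
    cc12 = float(np.corrcoef(ie, io)[0, 1])
    cc_star = float(np.sqrt(2 * cc12 / (1 + cc12))) if cc12 > 0 else float("nan")
    return cc12, cc_star


def equal_volume_edges(d_max: float, d_min: float, n_shells: int) -> np.ndarray:
    """Shell edges in d (Å) with d⁻³ evenly spaced (equal reciprocal volume)."""
    inv3 = np.linspace(d_max**-3, d_min**-3, n_shells + 1)
    return inv3 ** (-1.0 / 3.0)


@dataclass
class MergeStats:
    """Overall and per-shell merging statistics (Table-style layout)."""

    shells: pd.DataFrame      # one row per shell, high→low d
    overall: dict             # same columns for the full resolution range

    @property
    def outer_shell(self) -> dict:
        return self.shells.iloc[-1].to_dict()

    def table(self) -> pd.DataFrame:
        rows = self.shells.copy()
        overall = pd.DataFrame([self.overall], index=["overall"])
        return pd.concat([rows, overall])


def shell_statistics(
    halves: MergedHalves,
    n_shells: int = 10,
    merged: MergedSet | None = None,
) -> MergeStats:
    """Per-shell (equal-volume) and overall merging statistics.

    R_split/CC come from the half sets; completeness, multiplicity and mean
    I/σ from the full merge (built from the union of halves when ``merged``
    is not supplied — callers wanting the exact full merge should pass it).
    """
    if n_shells < 1:
        raise ValueError("n_shells must be >= 1")
    if merged is None:
        merged = _merge_of_halves(halves)
    hkl_c, ie, io = halves.common()
    d_c = merged.cell.d_spacing(hkl_c) if len(hkl_c) else np.empty(0)
    d_all = merged.d
    d_max, d_min = d_all.max(), d_all.min()
    edges = equal_volume_edges(float(d_max), float(d_min), n_shells)
    possible = unique_asu_hkl(merged.cell, merged.spacegroup, float(d_min))
    d_poss = merged.cell.d_spacing(possible)

    rows = []
    for i in range(n_shells):
        hi, lo = edges[i], edges[i + 1]  # hi = larger d
        in_shell = (d_all <= hi + 1e-9) & (d_all > lo - (1e-9 if i == n_shells - 1 else 0))
        in_common = (d_c <= hi + 1e-9) & (d_c > lo - (1e-9 if i == n_shells - 1 else 0)) \
            if len(d_c) else np.zeros(0, bool)
        n_poss = int(np.sum((d_poss <= hi + 1e-9) & (d_poss > lo - (1e-9 if i == n_shells - 1 else 0))))
        row = {
            "d_max": hi, "d_min": lo, "n_refl": int(in_shell.sum()),
            "completeness": 100.0 * in_shell.sum() / n_poss if n_poss else np.nan,
            "multiplicity": float(merged.multiplicity[in_shell].mean()) if in_shell.any() else np.nan,
            "i_over_sigma": float((merged.intensity[in_shell] / merged.sigma[in_shell]).mean())
            if in_shell.any() else np.nan,
        }
        if in_common.sum() >= 3:
            pair = MergedHalves(
                even=_subset_merged(halves.even, hkl_c[in_common]),
                odd=_subset_merged(halves.odd, hkl_c[in_common]),
            )
            try:
                row["rsplit"] = compute_rsplit(pair)
            except ValueError:
                row["rsplit"] = np.nan
            row["cc_half"], row["cc_star"] = compute_cc((ie[in_common], io[in_common]))
        else:
            row["rsplit"] = row["cc_half"] = row["cc_star"] = np.nan
        rows.append(row)
    shells = pd.DataFrame(rows)

    overall = {
        "d_max": float(d_max), "d_min": float(d_min), "n_refl": len(merged),
        "completeness": merged.completeness,
        "multiplicity": merged.mean_multiplicity,
        "i_over_sigma": float((merged.intensity / merged.sigma).mean()),
        "rsplit": compute_rsplit(halves) if len(ie) else np.nan,
    }
    overall["cc_half"], overall["cc_star"] = (
        compute_cc((ie, io)) if len(ie) >= 3 else (np.nan, np.nan)
    )
    return MergeStats(shells=shells, overall=overall)


def _merge_of_halves(halves: MergedHalves) -> MergedSet:
    """Weighted recombination of the two half merges (by multiplicity)."""
    e, o = halves.even, halves.odd
    idx = {}
    for src in (e, o):
        for i, h in enumerate(map(tuple, src.hkl)):
            idx.setdefault(h, []).append((src, i))
    hkl, inten, sig, mult = [], [], [], []
    for h, refs in idx.items():
        w = np.array([src.multiplicity[i] for src, i in refs])
        vals = np.array([src.intensity[i] for src, i in refs])
        sigs = np.array([src.sigma[i] for src, i in refs])
        hkl.append(h)
        inten.append(np.average(vals, weights=w))
        sig.append(np.sqrt(np.sum((w * sigs) ** 2)) / w.sum())
        mult.append(w.sum())
    hkl = np.array(hkl, int)
    d = e.cell.d_spacing(hkl)
    dm = float(d.min())
    possible = unique_asu_hkl(e.cell, e.spacegroup, dm)
    return MergedSet(
        hkl=hkl, intensity=np.array(inten), sigma=np.maximum(np.array(sig), 1e-12),
        multiplicity=np.array(mult), cell=e.cell, spacegroup=e.spacegroup,
        d_min=dm, completeness=100.0 * len(hkl) / len(possible),
        mean_multiplicity=float(np.mean(mult)), d=d,
    )


def _subset_merged(m: MergedSet, hkl: np.ndarray) -> MergedSet:
    imap = m.index_map()
    idx = [imap[tuple(h)] for h in hkl]
    return MergedSet(
        hkl=m.hkl[idx], intensity=m.intensity[idx], sigma=m.sigma[idx],
        multiplicity=m.multiplicity[idx], cell=m.cell, spacegroup=m.spacegroup,
        d_min=m.d_min, d=m.d[idx],
    )
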