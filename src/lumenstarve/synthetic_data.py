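"""Seeded synthetic-data generators with recorded ground truth.

Every input the pipeline consumes can be produced here with known
planted truth, so each analysis stage is testable end-to-end without
any external data:

* promoter sets with planted inverted repeats, overlapping-IR pairs or
  tandem+inverted repeats on an AT-rich background (GC 0.30 by default,
  approximating the organism's genome);
* triplicate light/dark probe-level expression with planted single-gene
  and operon fold changes;
* ATP shift series with a known light boost;
* radiotracer uptake series with known light/dark slopes;
* logistic-style growth with carbon-limited stationary phase and
  light-suppressed endogenous respiration.

All generators are pure functions of their seed and parameters.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .genome_io import GeneAnnotation, PromoterRegion, reverse_complement
from .microarray import ExpressionExperiment
from .motif_scan import InvertedRepeat, TandemInvertedRepeat
from .physiology import OxygenGrowthSeries, ShiftSeries, UptakeSeries
from . import reference

__all__ = [
    "PlantedTruth",
    "simulate_promoter_set",
    "simulate_expression_experiment",
    "simulate_atp_shift_series",
    "simulate_uptake_series",
    "simulate_growth_oxygen",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class PlantedTruth:
    """Registry of everything a generator planted, for round-trip checks."""

    seed: int
    params: dict[str, Any] = field(default_factory=dict)
    motifs: list[dict[str, Any]] = field(default_factory=list)
    de_effects: list[dict[str, Any]] = field(default_factory=list)
    physiology: dict[str, Any] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "PlantedTruth":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# promoter sets with planted repeats
# ---------------------------------------------------------------------------

class _ParityUnionFind:
    """Union-find over sequence positions with a same/complement parity bit."""

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.parity = [0] * n  # parity relative to parent

    def find(self, x: int) -> tuple[int, int]:
        if self.parent[x] == x:
            return x, 0
        root, par = self.find(self.parent[x])
        self.parent[x] = root
        self.parity[x] ^= par
        return root, self.parity[x]

    def union(self, x: int, y: int, rel: int) -> bool:
        """Impose value(x) = value(y) (rel=0) or complement (rel=1)."""
        rx, px = self.find(x)
        ry, py = self.find(y)
        if rx == ry:
            return (px ^ py) == rel
        self.parent[rx] = ry
        self.parity[rx] = px ^ py ^ rel
        return True


def _solve_segment(
    rng: np.random.Generator,
    length: int,
    constraints: Sequence[tuple[int, int, int]],
    probs: np.ndarray,
    bases: str = "ACGT",
) -> str | None:
    """Build a random segment satisfying same/complement position constraints.

    Returns None when the constraints are contradictory (a position
    forced equal to its own complement).
    """
    uf = _ParityUnionFind(length)
    for i, j, rel in constraints:
        if not uf.union(i, j, rel):
            return None
    out = [""] * length
    root_base: dict[int, str] = {}
    for pos in range(length):
        root, par = uf.find(pos)
        if root not in root_base:
            root_base[root] = bases[rng.choice(4, p=probs)]
        b = root_base[root]
        out[pos] = _COMP[b] if par else b
    return "".join(out)


def _ir_constraints(k: int, left: int, spacer: int) -> list[tuple[int, int, int]]:
    right = left + k + spacer
    return [(left + t, right + k - 1 - t, 1) for t in range(k)]


def _plant_segment(
    rng: np.random.Generator, spec: dict[str, Any], probs: np.ndarray
) -> tuple[str, dict[str, Any]]:
    """Build the motif-bearing segment for one plant spec.

    Returns (segment, descriptor-with-segment-local coordinates).
    Retries until the repeating oligo contains a C or G (and, for
    tandems, is not its own reverse complement).
    """
    kind = spec["kind"]
    k = int(spec.get("k", 6))
    for _ in range(200):
        if kind == "ir":
            spacer = int(spec.get("spacer", 2))
            seg_len = 2 * k + spacer
            seg = _solve_segment(rng, seg_len, _ir_constraints(k, 0, spacer), probs)
            if seg is None:
                continue
            oligo = seg[:k]
            if "C" in oligo or "G" in oligo:
                return seg, {"kind": "ir", "k": k, "left": 0, "right": k + spacer, "oligo": oligo}
        elif kind == "pair":
            # two overlapping IRs in the (k-1-k)x2 phase: the second IR's
            # left arm starts one base before the first IR's right arm.
            spacer = 1
            seg_len = 3 * k + 2 * spacer - 1
            cons = _ir_constraints(k, 0, spacer) + _ir_constraints(k, k + spacer - 1, spacer)
            seg = _solve_segment(rng, seg_len, cons, probs)
            if seg is None:
                continue
            o1, o2 = seg[:k], seg[k + spacer - 1 : 2 * k + spacer - 1]
            if ("C" in o1 or "G" in o1) and ("C" in o2 or "G" in o2):
                return seg, {
                    "kind": "pair", "k": k, "spacer": spacer,
                    "left1": 0, "right1": k + spacer,
                    "left2": k + spacer - 1, "right2": 2 * k + 2 * spacer - 1,
                    "oligo1": o1, "oligo2": o2,
                }
        elif kind == "tandem":
            g1 = int(spec.get("gap1", 1))
            g2 = int(spec.get("gap2", 2))
            p2, p3 = k + g1, 2 * k + g1 + g2
            seg_len = p3 + k
            cons = [(t, p2 + t, 0) for t in range(k)]  # second copy forward
            cons += [(t, p3 + k - 1 - t, 1) for t in range(k)]  # last copy revcomp
            seg = _solve_segment(rng, seg_len, cons, probs)
            if seg is None:
                continue
            oligo = seg[:k]
            if ("C" in oligo or "G" in oligo) and reverse_complement(oligo) != oligo:
                return seg, {
                    "kind": "tandem", "k": k, "starts": [0, p2, p3],
                    "orientations": ["forward", "forward", "revcomp"], "oligo": oligo,
                }
        else:
            raise ValueError(f"unknown plant kind {kind!r}")
    raise RuntimeError(f"could not build a valid {kind} segment")


def _screen(seq: str, descriptor: dict[str, Any] | None, kmin: int, kmax: int) -> bool:
    """Rejection screen: the brute-force reference must see exactly the plant."""
    survivors = reference.brute_filter_subsumed(
        [h for h in reference.brute_inverted_repeats(seq, kmin, kmax)
         if "C" in h.oligo or "G" in h.oligo]
    )
    pairs = reference.brute_overlapping_pairs(survivors)
    tandems = reference.brute_tandem_inverted(seq, kmin, kmax)
    if descriptor is None:
        return not survivors and not tandems
    kind = descriptor["kind"]
    if kind == "ir":
        want = {(descriptor["oligo"], descriptor["k"], descriptor["left"], descriptor["right"])}
        got = {(h.oligo, h.k, h.left_start, h.right_start) for h in survivors}
        return got == want and not pairs and not tandems
    if kind == "pair":
        want = {
            (descriptor["oligo1"], descriptor["k"], descriptor["left1"], descriptor["right1"]),
            (descriptor["oligo2"], descriptor["k"], descriptor["left2"], descriptor["right2"]),
        }
        got = {(h.oligo, h.k, h.left_start, h.right_start) for h in survivors}
        return got == want and len(pairs) == 1 and not tandems
    if kind == "tandem":
        want = {(descriptor["oligo"], descriptor["k"], tuple(descriptor["starts"]))}
        got = {(t.oligo, t.k, t.starts) for t in tandems}
        return got == want
    raise ValueError(kind)


def simulate_promoter_set(
    n_seqs: int,
    length: int = 150,
    plant_spec: dict[str, Any] | Sequence[dict[str, Any] | None] | None = None,
    gc: float = 0.30,
    seed: int = 0,
    kmin: int = 6,
    kmax: int = 15,
    max_retries: int = 500,
) -> tuple[list[PromoterRegion], PlantedTruth]:
    """Generate promoter-length sequences with optional planted motifs.

    ``plant_spec`` is either one spec dict applied to every sequence, a
    per-sequence list (None entries stay background-only), or None.
    Spec dicts: ``{"kind": "ir", "k":..., "spacer":...}``,
    ``{"kind": "pair", "k":...}`` or ``{"kind": "tandem", "k":...,
    "gap1":..., "gap2":...}``.  Each sequence is re-scanned with the
    brute-force reference and regenerated until exactly the planted
    motifs (and nothing else of the planted classes) are present.
    """
    if n_seqs < 0:
        raise ValueError("n_seqs must be >= 0")
    if isinstance(plant_spec, dict) or plant_spec is None:
        specs: list[dict[str, Any] | None] = [plant_spec] * n_seqs
    else:
        specs = list(plant_spec)
        if len(specs) != n_seqs:
            raise ValueError("per-sequence plant_spec must have n_seqs entries")
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    rng = np.random.default_rng(seed)
    truth = PlantedTruth(
        seed=seed,
        params={"n_seqs": n_seqs, "length": length, "gc": gc, "kmin": kmin, "kmax": kmax},
    )
    promoters: list[PromoterRegion] = []
    for i in range(n_seqs):
        spec = specs[i]
        seq_id = f"syn{i:04d}"
        for attempt in range(max_retries):
            if spec is None:
                seq = "".join("ACGT"[b] for b in rng.choice(4, size=length, p=probs))
                descriptor = None
            else:
                segment, local = _plant_segment(rng, spec, probs)
                if len(segment) > length:
                    raise ValueError(f"plant spec {spec} does not fit in length {length}")
                offset = int(rng.integers(0, length - len(segment) + 1))
                background = "".join(
                    "ACGT"[b] for b in rng.choice(4, size=length - len(segment), p=probs)
                )
                seq = background[:offset] + segment + background[offset:]
                descriptor = _shift_descriptor(local, offset)
            if _screen(seq, descriptor, kmin, kmax):
                break
        else:
            raise RuntimeError(f"sequence {seq_id}: rejection screen failed {max_retries} times")
        promoters.append(
            PromoterRegion(seq_id, seq, 1, length, "+", truncated=False)
        )
        if descriptor is not None:
            truth.motifs.append({"seq_id": seq_id, **descriptor})
    return promoters, truth


def _shift_descriptor(local: dict[str, Any], offset: int) -> dict[str, Any]:
    d = dict(local)
    for key in ("left", "right", "left1", "right1", "left2", "right2"):
        if key in d:
            d[key] = d[key] + offset
    if "starts" in d:
        d["starts"] = [p + offset for p in d["starts"]]
    return d


def planted_inverted_repeats(truth: PlantedTruth) -> list[InvertedRepeat]:
    """Materialize planted IRs (including pair members) as scanner objects."""
    out: list[InvertedRepeat] = []
    for m in truth.motifs:
        if m["kind"] == "ir":
            out.append(InvertedRepeat(m["oligo"], m["k"], m["left"], m["right"], m["seq_id"]))
        elif m["kind"] == "pair":
            out.append(InvertedRepeat(m["oligo1"], m["k"], m["left1"], m["right1"], m["seq_id"]))
            out.append(InvertedRepeat(m["oligo2"], m["k"], m["left2"], m["right2"], m["seq_id"]))
    return out


def planted_tandems(truth: PlantedTruth) -> list[TandemInvertedRepeat]:
    return [
        TandemInvertedRepeat(
            m["oligo"], m["k"], tuple(m["starts"]), tuple(m["orientations"]), m["seq_id"]
        )
        for m in truth.motifs
        if m["kind"] == "tandem"
    ]


# ---------------------------------------------------------------------------
# expression experiments
# ---------------------------------------------------------------------------

def simulate_expression_experiment(
    n_genes: int,
    n_reps: int = 3,
    de_spec: Sequence[dict[str, Any]] = (),
    noise_sd_log2: float = 0.25,
    probes_per_gene: int = 8,
    baseline_mean_log2: float = 7.0,
    baseline_sd_log2: float = 1.5,
    probe_effect_sd_log2: float = 0.5,
    operon_gap: int = 5,
    intergenic_gap: int = 200,
    gene_length: int = 900,
    seed: int = 0,
) -> tuple[ExpressionExperiment, list[GeneAnnotation], PlantedTruth]:
    """Simulate a triplicate light/dark probe-level experiment.

    ``de_spec`` entries: ``{"genes": [...], "fold": 2.5, "direction":
    "up_in_light"}``; entries with several genes are laid out as
    consecutive same-strand genes with tiny intergenic gaps so the
    operon grouper finds them, all other genes are separated by
    ``intergenic_gap``.  The log2 signal of probe p of gene g on array s
    is baseline(g) + probe_effect(p) + treatment_effect(g, s) + noise;
    exported intensities are linear scale.
    """
    if n_reps < 2:
        raise ValueError("need n_reps >= 2")
    for entry in de_spec:
        if entry["fold"] <= 0:
            raise ValueError("planted folds must be positive")
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]

    # lay out genes on a virtual chromosome; operon members adjacent
    operon_members: dict[str, int] = {}
    for idx, entry in enumerate(de_spec):
        if len(entry["genes"]) > 1:
            for g in entry["genes"]:
                operon_members[g] = idx
    annotations: list[GeneAnnotation] = []
    pos = 1
    prev_operon: int | None = None
    for g in gene_ids:
        op = operon_members.get(g)
        if annotations:
            gap = operon_gap if (op is not None and op == prev_operon) else intergenic_gap
            pos = annotations[-1].end + 1 + gap
        annotations.append(GeneAnnotation(g, pos, pos + gene_length - 1, "+"))
        prev_operon = op

    effects = np.zeros(n_genes)
    truth = PlantedTruth(
        seed=seed,
        params={
            "n_genes": n_genes, "n_reps": n_reps, "noise_sd_log2": noise_sd_log2,
            "probes_per_gene": probes_per_gene,
        },
    )
    index_of = {g: i for i, g in enumerate(gene_ids)}
    for entry in de_spec:
        sign = 1.0 if entry.get("direction", "up_in_light") == "up_in_light" else -1.0
        for g in entry["genes"]:
            effects[index_of[g]] = sign * np.log2(entry["fold"])
        truth.de_effects.append(
            {
                "genes": list(entry["genes"]),
                "fold": float(entry["fold"]),
                "direction": entry.get("direction", "up_in_light"),
                "is_operon": len(entry["genes"]) > 1,
            }
        )

    sample_ids = [f"light_{r+1}" for r in range(n_reps)] + [f"dark_{r+1}" for r in range(n_reps)]
    treatments = ["light"] * n_reps + ["dark"] * n_reps
    baselines = rng.normal(baseline_mean_log2, baseline_sd_log2, size=n_genes)
    probe_ids: list[str] = []
    probe_gene: list[str] = []
    blocks: list[np.ndarray] = []
    for gi, g in enumerate(gene_ids):
        probe_eff = rng.normal(0.0, probe_effect_sd_log2, size=probes_per_gene)
        noise = rng.normal(0.0, noise_sd_log2, size=(probes_per_gene, 2 * n_reps))
        treat = np.array([effects[gi] if t == "light" else 0.0 for t in treatments])
        log2_signal = baselines[gi] + probe_eff[:, None] + treat[None, :] + noise
        blocks.append(log2_signal)
        probe_ids.extend(f"{g}_p{p}" for p in range(probes_per_gene))
        probe_gene.extend([g] * probes_per_gene)
    log2_all = np.vstack(blocks)
    intensities = pd.DataFrame(2.0**log2_all, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids)
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "treatment": treatments,
            "replicate": list(range(1, n_reps + 1)) * 2,
        }
    )
    experiment = ExpressionExperiment(
        intensities, pd.Series(probe_gene, index=intensities.index, name="gene_id"), samples
    )
    return experiment, annotations, truth


def write_expression_tsv(
    experiment: ExpressionExperiment, intensities_path: str | Path, samples_path: str | Path
) -> None:
    tab = experiment.intensities.copy()
    tab.insert(0, "gene_id", experiment.probe_to_gene)
    tab.to_csv(intensities_path, sep="\t")
    experiment.samples.to_csv(samples_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# physiology series
# ---------------------------------------------------------------------------

def simulate_atp_shift_series(
    n_shifts: int = 4,
    true_boost_percent: float = 36.0,
    noise_cv: float = 0.05,
    dark_level: float = 1e-18,
    period_min: float = 5.5,
    sample_offset_min: float = 5.0,
    seed: int = 0,
) -> tuple[ShiftSeries, PlantedTruth]:
    """Alternating dark/light ATP-per-cell series with a known light boost.

    Each light reading equals the preceding dark reading times
    (1 + boost/100); both carry multiplicative lognormal noise with the
    given coefficient of variation.  Timestamps follow the experimental
    cadence: the lamp toggles every ``period_min`` minutes and samples
    are drawn ``sample_offset_min`` minutes into each period.
    """
    if n_shifts < 1:
        raise ValueError("need >= 1 dark->light shift")
    if true_boost_percent <= -100:
        raise ValueError("boost must exceed -100%")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2)) if noise_cv > 0 else 0.0

    def jitter() -> float:
        if sigma == 0.0:
            return 1.0
        return float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))

    times, phases, values = [], [], []
    for s in range(n_shifts):
        t_dark = 2 * s * period_min + sample_offset_min
        dark_val = dark_level * jitter()
        times.append(t_dark)
        phases.append("dark")
        values.append(dark_val)
        times.append(t_dark + period_min)
        phases.append("light")
        values.append(dark_val * (1 + true_boost_percent / 100.0) * jitter())
    series = ShiftSeries(np.array(times), tuple(phases), np.array(values))
    truth = PlantedTruth(
        seed=seed,
        params={"n_shifts": n_shifts, "noise_cv": noise_cv},
        physiology={"true_boost_percent": true_boost_percent},
    )
    return series, truth


def simulate_uptake_series(
    true_rate_light: float = 1.65,
    true_rate_dark: float = 1.0,
    control_rate: float = 0.0,
    baseline_dpm: float = 100.0,
    n_timepoints: int = 5,
    interval_min: float = 10.0,
    n_replicates: int = 3,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[UptakeSeries, UptakeSeries, PlantedTruth]:
    """Paired light/dark radiotracer series with killed controls.

    Live counts follow baseline + (rate + control_rate) * t, the killed
    control baseline + control_rate * t, with multiplicative lognormal
    noise and triplicate filtration per timepoint.
    """
    if n_timepoints < 3:
        raise ValueError("need >= 3 timepoints")
    if min(true_rate_light, true_rate_dark, control_rate) < 0:
        raise ValueError("rates must be non-negative")
    rng = np.random.default_rng(seed)
    t = np.arange(n_timepoints) * interval_min
    sigma = np.sqrt(np.log1p(noise_cv**2)) if noise_cv > 0 else 0.0

    def noisy(mean: np.ndarray) -> np.ndarray:
        base = np.repeat(mean[:, None], n_replicates, axis=1)
        if sigma == 0.0:
            return base
        return base * np.exp(rng.normal(-0.5 * sigma**2, sigma, size=base.shape))

    series = []
    for rate in (true_rate_light, true_rate_dark):
        live = noisy(baseline_dpm + (rate + control_rate) * t)
        control = noisy(baseline_dpm + control_rate * t)
        series.append(UptakeSeries(t, live, control))
    truth = PlantedTruth(
        seed=seed,
        params={"n_timepoints": n_timepoints, "noise_cv": noise_cv},
        physiology={
            "true_rate_light": true_rate_light,
            "true_rate_dark": true_rate_dark,
            "true_percent_difference": (
                100.0 * (true_rate_light - true_rate_dark) / true_rate_dark
                if true_rate_dark > 0
                else None
            ),
        },
    )
    return series[0], series[1], truth


def simulate_growth_oxygen(
    mu: float = 0.04,
    n0: float = 5.0e7,
    n_max: float = 4.7e8,
    y_o2_umol_per_cell_ml: float = 2.5e-7,
    r_endog_amol_per_cell_h: float = 3.0,
    light_suppression: float = 0.5,
    o2_start: float = 250.0,
    dt: float = 0.5,
    t_end: float = 96.0,
    obs_interval: float = 12.0,
    n_bottles: int = 4,
    obs_noise_o2: float = 0.0,
    obs_noise_cells_cv: float = 0.0,
    seed: int = 0,
) -> tuple[OxygenGrowthSeries, OxygenGrowthSeries, PlantedTruth]:
    """Minimal carbon-budget growth/respiration model, light vs dark.

    Cells grow exponentially at ``mu`` (1/h) until the carbon pool,
    expressed as the supportable density ``n_max`` (cells/mL), is
    exhausted; each new cell costs ``y_o2_umol_per_cell_ml`` µmol/L of
    O2.  After carbon exhaustion the density stays constant and O2
    declines through endogenous respiration at ``r_endog`` amol per cell
    per hour in the dark, suppressed by the fraction
    ``light_suppression`` in the light.  Growth trajectories are
    identical in both conditions.  Observations are taken every
    ``obs_interval`` hours with optional normal noise on O2 readings and
    lognormal noise on cell counts.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (0.0 <= light_suppression <= 1.0):
        raise ValueError("light_suppression must lie in [0, 1]")
    if min(mu, n0, n_max, y_o2_umol_per_cell_ml, r_endog_amol_per_cell_h) <= 0:
        raise ValueError("model parameters must be positive")
    rng = np.random.default_rng(seed)
    n_steps = int(round(t_end / dt)) + 1
    t = np.arange(n_steps) * dt
    cells = np.empty(n_steps)
    o2 = {"light": np.empty(n_steps), "dark": np.empty(n_steps)}
    cells[0] = n0
    o2["light"][0] = o2["dark"][0] = o2_start
    growth = np.exp(mu * dt)
    for i in range(1, n_steps):
        new_n = min(cells[i - 1] * growth, n_max)
        d_cells = new_n - cells[i - 1]
        cells[i] = new_n
        growth_o2 = y_o2_umol_per_cell_ml * d_cells
        # per-cell endogenous drawdown in µmol/L/h: amol/cell/h * cells/mL / 1e9
        endo = r_endog_amol_per_cell_h * new_n / 1e9 * dt
        if d_cells > 0:
            endo = 0.0  # endogenous respiration applies in stationary phase only
        o2["dark"][i] = max(o2["dark"][i - 1] - growth_o2 - endo, 0.0)
        o2["light"][i] = max(
            o2["light"][i - 1] - growth_o2 - endo * (1.0 - light_suppression), 0.0
        )
    obs_idx = [i for i in range(n_steps) if abs(t[i] % obs_interval) < dt / 2 or i == n_steps - 1]
    obs_idx = sorted(set(obs_idx))
    t_obs = t[obs_idx]

    def observe(trace: np.ndarray) -> np.ndarray:
        base = np.repeat(trace[obs_idx, None], n_bottles, axis=1)
        if obs_noise_o2 > 0:
            base = np.clip(base + rng.normal(0.0, obs_noise_o2, size=base.shape), 0.0, None)
        return base

    def observe_cells() -> np.ndarray:
        base = np.repeat(cells[obs_idx, None], n_bottles, axis=1)
        if obs_noise_cells_cv > 0:
            sigma = np.sqrt(np.log1p(obs_noise_cells_cv**2))
            base = base * np.exp(rng.normal(-0.5 * sigma**2, sigma, size=base.shape))
        return base

    light = OxygenGrowthSeries(t_obs, observe(o2["light"]), observe_cells(), "light_cycle")
    dark = OxygenGrowthSeries(t_obs, observe(o2["dark"]), observe_cells(), "dark")
    truth = PlantedTruth(
        seed=seed,
        params={"mu": mu, "n0": n0, "n_max": n_max, "dt": dt, "t_end": t_end},
        physiology={
            "light_suppression": light_suppression,
            "r_endog_amol_per_cell_h": r_endog_amol_per_cell_h,
            "stationary_start_h": float(np.log(n_max / n0) / mu),
        },
    )
    return light, dark, truth
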