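"""Synthetic SMFS data: WLC sawtooth curves, spurious traces, mixtures.

The generator emulates the event taxonomy of a native-membrane pulling
experiment at the level the analysis sees it:

* *sawtooth unfolding curves* are piecewise WLC: the protein template lists
  the contour lengths of its obligatory unfolding intermediates and the
  rupture force of each; the force follows the WLC branch of the current
  intermediate until its rupture force is reached, then drops to baseline
  (instantaneously - the analysis never uses the drop shape).  A short
  adhesive dip precedes the contact point and a flat noisy baseline follows
  the last rupture.  Gaussian force noise is added throughout, and the curve
  is exported as a raw piezo trace (deflection folded back in) so the
  preprocessing transform is exercised end to end.
* *premature detachment* truncates the sawtooth at a uniformly chosen
  intermediate (about 23% of full unfoldings in the literature).
* *spurious traces* are sums of 1-3 independent random sawtooths, emulating
  simultaneous attachment of several proteins: individually WLC-like but
  jointly inconsistent with a single chain.
* *tether traces* are constant-force plateaus.

``simulate_dataset`` draws templates per curve from relative abundances
(multinomial), mixes in spurious/tether fractions, and keeps ground-truth
labels.  ``synth_proteome`` builds the matching proteome table: template
residue counts follow from the last-barrier contour length through the
0.89 x 0.4 nm/residue relations, loop centers sit at the unfolding barriers,
and decoys get lengths well separated from every template.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fd_io import CurveSet, DEFAULT_SPRING_CONSTANT, ForceDistanceCurve, ProteinRecord
from .wlc_transform import WlcParams, wlc_force, _relative_extension

RAW_PITCH_NM = 0.5  # raw sampling pitch, finer than the 1-nm analysis grid
ADHESION_NM = 5.0
ADHESION_PN = -50.0
LC_SCALE = 0.89  # measured Lc_max as a fraction of nominal contour length
NM_PER_RESIDUE = 0.4


class TemplateError(ValueError):
    """Template whose rupture sequence is not realisable."""


@dataclass
class ProteinTemplate:
    """Unfolding fingerprint of a synthetic membrane protein."""

    template_id: str
    barrier_lcs: list[float]  # ascending contour lengths of intermediates, nm
    rupture_forces: list[float]  # rupture force per barrier, pN
    ss_class: str = "helix"
    abundance: float = 1.0

    def __post_init__(self) -> None:
        if len(self.barrier_lcs) != len(self.rupture_forces):
            raise TemplateError(f"{self.template_id}: barriers/forces length mismatch")
        if list(self.barrier_lcs) != sorted(self.barrier_lcs):
            raise TemplateError(f"{self.template_id}: barriers must ascend")
        if any(not 30 <= f <= 500 for f in self.rupture_forces):
            raise TemplateError(f"{self.template_id}: rupture forces outside 30-500 pN")

    @property
    def n_residues(self) -> int:
        return int(round(self.barrier_lcs[-1] / (LC_SCALE * NM_PER_RESIDUE)))

    def rupture_extensions(self, params: WlcParams) -> np.ndarray:
        """Extension at which each barrier ruptures; must be increasing."""
        xs = np.array(
            [
                lc * _relative_extension(f, params)
                for lc, f in zip(self.barrier_lcs, self.rupture_forces)
            ]
        )
        if np.any(np.diff(xs) <= 0):
            raise TemplateError(
                f"{self.template_id}: rupture force unreachable before next barrier"
            )
        return xs


@dataclass
class SimulationConfig:
    """Study conditions of a simulated batch.

    noise_sd 10 pN reflects a typical AFM baseline at desk settings; the
    premature-detachment fraction follows the ~23% literature figure.
    """

    noise_sd: float = 10.0
    spurious_fraction: float = 0.0
    premature_detach_fraction: float = 0.23
    tether_fraction: float = 0.0
    seed: int = 0
    spring_constant: float = DEFAULT_SPRING_CONSTANT
    wlc: WlcParams = field(default_factory=WlcParams)

    def __post_init__(self) -> None:
        for name in ("spurious_fraction", "premature_detach_fraction", "tether_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


def _sawtooth_force(x: np.ndarray, template: ProteinTemplate, params: WlcParams) -> np.ndarray:
    """Noiseless piecewise-WLC force on extension grid x >= 0."""
    xs = template.rupture_extensions(params)
    force = np.zeros_like(x)
    prev = 0.0
    for lc, f_rup, x_rup in zip(template.barrier_lcs, template.rupture_forces, xs):
        sel = (x > prev) & (x <= x_rup) & (x < lc)
        force[sel] = wlc_force(x[sel], lc, params)
        prev = x_rup
    return force


def _truncate(template: ProteinTemplate, n_keep: int) -> ProteinTemplate:
    return ProteinTemplate(
        template_id=template.template_id,
        barrier_lcs=list(template.barrier_lcs[:n_keep]),
        rupture_forces=list(template.rupture_forces[:n_keep]),
        ss_class=template.ss_class,
        abundance=template.abundance,
    )


def _emit_curve(
    x: np.ndarray,
    force: np.ndarray,
    curve_id: str,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    sample_id: str = "sim",
) -> ForceDistanceCurve:
    if cfg.noise_sd > 0:
        noisy = force + rng.normal(0.0, cfg.noise_sd, size=len(force))
        noisy = noisy + rng.uniform(-20.0, 20.0)  # baseline offset, zeroed in Block 1
    else:
        noisy = force  # noiseless mode: ideal curve for construction identities
    z = x + noisy / cfg.spring_constant  # fold the deflection back in
    return ForceDistanceCurve(
        curve_id=curve_id,
        z=z,
        force=noisy,
        spring_constant=cfg.spring_constant,
        sample_id=sample_id,
        is_tss=False,
    )


def _extension_grid(x_last: float) -> np.ndarray:
    tail = max(60.0, 0.4 * x_last)
    return np.arange(-ADHESION_NM, x_last + tail, RAW_PITCH_NM)


def simulate_curve(
    template: ProteinTemplate,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    curve_id: str = "sim-0",
    n_barriers_keep: int | None = None,
) -> ForceDistanceCurve:
    """One sawtooth unfolding curve; deterministic given the rng state.

    ``n_barriers_keep`` truncates the template (premature detachment).
    """
    tpl = template if n_barriers_keep is None else _truncate(template, n_barriers_keep)
    xs = tpl.rupture_extensions(cfg.wlc)
    x = _extension_grid(float(xs[-1]))
    force = np.where(x < 0, ADHESION_PN, 0.0)
    pos = x >= 0
    force[pos] = _sawtooth_force(x[pos], tpl, cfg.wlc)
    return _emit_curve(x, force, curve_id, cfg, rng)


def simulate_spurious(
    cfg: SimulationConfig, rng: np.random.Generator, curve_id: str = "spur-0"
) -> ForceDistanceCurve:
    """Sum of overlapping random sawtooths (multiple attachment)."""
    n_chains = int(rng.integers(2, 5))
    parts = []
    for _ in range(n_chains):
        for _attempt in range(20):
            n_br = int(rng.integers(1, 4))
            lcs = np.sort(rng.uniform(30.0, 260.0, size=n_br))
            lcs = np.maximum.accumulate(lcs + np.arange(n_br) * 15.0)
            forces = rng.uniform(60.0, 250.0, size=n_br)
            try:
                tpl = ProteinTemplate("rand", list(lcs), list(forces))
                tpl.rupture_extensions(cfg.wlc)
                parts.append(tpl)
                break
            except TemplateError:
                continue
    x_last = max(float(t.rupture_extensions(cfg.wlc)[-1]) for t in parts)
    x = _extension_grid(x_last)
    force = np.where(x < 0, ADHESION_PN, 0.0)
    pos = x >= 0
    for tpl in parts:
        force[pos] += _sawtooth_force(x[pos], tpl, cfg.wlc)
    return _emit_curve(x, force, curve_id, cfg, rng)


def simulate_tether(
    cfg: SimulationConfig, rng: np.random.Generator, curve_id: str = "teth-0"
) -> ForceDistanceCurve:
    """Constant-force membrane-tether plateau."""
    length = float(rng.uniform(50.0, 200.0))
    plateau = float(rng.uniform(40.0, 80.0))
    x = _extension_grid(length)
    force = np.where(x < 0, ADHESION_PN, np.where(x <= length, plateau, 0.0))
    return _emit_curve(x, force, curve_id, cfg, rng)


def simulate_noise_trace(
    cfg: SimulationConfig, rng: np.random.Generator, curve_id: str = "noise-0", length: float = 200.0
) -> ForceDistanceCurve:
    """Pure-baseline trace (contact dip then noise), for filter calibration."""
    x = np.arange(-ADHESION_NM, length, RAW_PITCH_NM)
    force = np.where(x < 0, ADHESION_PN, 0.0)
    return _emit_curve(x, force, curve_id, cfg, rng)


def simulate_dataset(
    templates: list[ProteinTemplate],
    abundances: list[float],
    n_total: int,
    cfg: SimulationConfig,
) -> tuple[CurveSet, dict[str, str]]:
    """Abundance-weighted mixture of template curves plus spurious/tether
    traces; returns the curves and ground-truth labels per curve id."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    ab = np.asarray(abundances, dtype=float)
    if len(ab) != len(templates) or np.any(ab < 0) or ab.sum() == 0:
        raise ValueError("abundances must be nonnegative, one per template, not all zero")
    p = ab / ab.sum()
    rng = np.random.default_rng(cfg.seed)
    curves: list[ForceDistanceCurve] = []
    labels: dict[str, str] = {}
    for i in range(n_total):
        cid = f"sim-{i:05d}"
        u = rng.random()
        if u < cfg.spurious_fraction:
            curves.append(simulate_spurious(cfg, rng, cid))
            labels[cid] = "spurious"
            continue
        if u < cfg.spurious_fraction + cfg.tether_fraction:
            curves.append(simulate_tether(cfg, rng, cid))
            labels[cid] = "tether"
            continue
        tpl = templates[int(rng.choice(len(templates), p=p))]
        n_keep = None
        if len(tpl.barrier_lcs) > 1 and rng.random() < cfg.premature_detach_fraction:
            n_keep = int(rng.integers(1, len(tpl.barrier_lcs)))
        curves.append(simulate_curve(tpl, cfg, rng, cid, n_barriers_keep=n_keep))
        labels[cid] = tpl.template_id
    return CurveSet(curves=curves, provenance=["synthetic"]), labels


def example_templates(n: int = 3) -> list[ProteinTemplate]:
    """Well-separated template presets (lengths differ by > 20%)."""
    presets = [
        ProteinTemplate("tplA", [30.0, 55.0, 80.0], [120.0, 150.0, 180.0]),
        ProteinTemplate("tplB", [45.0, 90.0, 130.0], [100.0, 140.0, 160.0], ss_class="sheet"),
        ProteinTemplate("tplC", [60.0, 120.0, 210.0], [90.0, 130.0, 170.0]),
        ProteinTemplate("tplD", [40.0, 95.0, 160.0, 285.0], [110.0, 130.0, 150.0, 170.0], ss_class="mixed"),
        ProteinTemplate("tplE", [55.0, 110.0, 375.0], [95.0, 125.0, 155.0]),
    ]
    if not 1 <= n <= len(presets):
        raise ValueError(f"n must be in [1, {len(presets)}]")
    return presets[:n]


def random_template(
    rng: np.random.Generator,
    template_id: str,
    last_lc: float,
    n_barriers: int | None = None,
    wlc: WlcParams | None = None,
) -> ProteinTemplate:
    """Random realisable template with a prescribed final barrier length."""
    wlc = wlc or WlcParams()
    if n_barriers is None:
        # short proteins cannot host many well-separated intermediates
        cap = max(2, min(4, int(last_lc // 50)))
        n_barriers = int(rng.integers(2, cap + 1))
    min_gap = min(15.0, 0.15 * last_lc)
    for _ in range(200):
        inner = np.sort(rng.uniform(0.2, 0.8, size=n_barriers - 1)) * last_lc
        if len(inner) > 1 and np.any(np.diff(inner) < min_gap):
            continue
        lcs = list(inner) + [last_lc]
        ss_class = str(rng.choice(["helix", "sheet", "mixed"]))
        # rupture forces follow the class-dependent stability trend:
        # beta-sheets unfold at higher forces than alpha-helices
        median = {"helix": 110.0, "sheet": 200.0, "mixed": 150.0}[ss_class]
        forces = np.clip(
            median * np.exp(rng.normal(0.0, 0.25, size=n_barriers)), 60.0, 450.0
        ).tolist()
        try:
            tpl = ProteinTemplate(template_id, lcs, forces, ss_class=ss_class)
            tpl.rupture_extensions(wlc)
            return tpl
        except TemplateError:
            continue
    raise TemplateError(f"{template_id}: could not realise a template")


def synth_proteome(
    templates: list[ProteinTemplate],
    n_decoys: int = 0,
    rng: np.random.Generator | None = None,
    separation_factor: float = 1.35,
) -> list[ProteinRecord]:
    """Proteome table pairing the templates with random decoy proteins.

    Template records derive residue counts from the last-barrier contour
    length (Lc_max ~ 0.89 * 0.4 nm/residue * n_residues) and place loop
    centers at the unfolding barriers.  Decoy lengths stay at least
    ``separation_factor`` away (multiplicatively) from every template.
    """
    rng = rng or np.random.default_rng(0)
    records = []
    for tpl in templates:
        nres = tpl.n_residues
        lmax = nres * NM_PER_RESIDUE
        loops = [min(lc, lmax) for lc in tpl.barrier_lcs]
        records.append(
            ProteinRecord(
                protein_id=tpl.template_id,
                n_residues=nres,
                abundance=tpl.abundance,
                is_membrane=1,
                ss_class=tpl.ss_class,
                final_domain_nm=0.0,
                loop_centers_nm=loops,
            )
        )
    template_lengths = [tpl.barrier_lcs[-1] / LC_SCALE for tpl in templates]
    made = 0
    attempts = 0
    while made < n_decoys and attempts < 1000 * max(n_decoys, 1):
        attempts += 1
        L = float(np.exp(rng.uniform(np.log(40.0), np.log(500.0))))
        if any(
            1.0 / separation_factor < L / tl < separation_factor for tl in template_lengths
        ):
            continue
        nres = max(int(round(L / NM_PER_RESIDUE)), 30)
        lmax = nres * NM_PER_RESIDUE
        n_loops = int(rng.integers(2, 6))
        loops = sorted(float(v) for v in rng.uniform(10.0, 0.9 * lmax, size=n_loops))
        records.append(
            ProteinRecord(
                protein_id=f"decoy-{made:03d}",
                n_residues=nres,
                abundance=float(rng.uniform(0.3, 3.0)),
                is_membrane=1,
                ss_class=str(rng.choice(["helix", "sheet", "mixed", "unknown"])),
                final_domain_nm=0.0,
                loop_centers_nm=loops,
            )
        )
        made += 1
    return records
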