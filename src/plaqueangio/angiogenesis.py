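"""Stochastic nine-point (2D9P) discrete angiogenesis on the plaque grid.

The capillary network grows from 12 vasa-vasorum sprout tips.  Each step every
active tip either stays put or moves to one of its eight neighbours; the nine
probabilities come from the explicit nine-point discretization of the
endothelial-cell transport equation (random motility + chemotaxis up the VEGF
gradient + haptotaxis up the ECM gradient).  Tips may branch into two
daughters -- only at existing tips, only after a maturation age, only with
local free space, and with a probability that increases with local VEGF.  A
tip that lands on an occupied node fuses with the network (anastomosis) and
stops growing; in tip-to-tip fusion only the elder tip survives.

Topology bookkeeping follows the two-binary-matrix scheme: ``A`` marks
occupied grid nodes, ``B`` marks vessel segments per node per direction
(stored reciprocally at both endpoints).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fields import ChemicalState, StepCoefficients, step_fields
from .geometry import PlaqueDomain, Region

#: Direction table, index k = 1..8: four axial then four diagonal moves.
OFFSETS = np.array(
    [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1), (-1, 1), (1, -1), (-1, -1), (1, 1)],
    dtype=int,
)
#: Squared step length per direction (1 axial, 2 diagonal); index 0 unused.
LEN2 = np.array([0.0, 1, 1, 1, 1, 2, 2, 2, 2])
#: Opposite direction of k (for reciprocal segment storage).
OPPOSITE = np.array([0, 2, 1, 4, 3, 6, 5, 8, 7], dtype=int)

R0_CM = 4.0e-4  # baseline capillary radius, 4 um


class TipBoundaryError(ValueError):
    """Raised when motion coefficients are requested on the boundary margin."""


@dataclass(frozen=True)
class BranchConfig:
    """Branching rule: VEGF tiers, maturation age and the MVD knob.

    ``tiers`` maps the local VEGF level (relative to the initial shoulder
    maximum) to a per-step branch probability through a monotone step
    function; ``scale`` multiplies the tier probabilities (clipped at 1) and
    is the knob that produces the low/basic/high microvessel-density groups.
    """

    thresholds: tuple = (0.3, 0.5, 0.7, 0.8)
    probs: tuple = (0.0, 0.2, 0.3, 0.4, 1.0)
    age_gate: int = 15
    scale: float = 1.0

    def probability(self, ratio: float) -> float:
        i = int(np.searchsorted(np.asarray(self.thresholds), ratio, side="right"))
        return min(1.0, self.probs[i] * self.scale)


@dataclass
class Tip:
    x: int
    y: int
    age: int = 0
    branch_id: int = 0
    active: bool = True
    landed_on_occupied: bool = False


@dataclass
class VesselNetwork:
    """Discrete capillary network on the plaque grid.

    Segments are stored as parallel lists of endpoint coordinates, lengths
    (cm) and radii (cm); ``A``/``B`` mirror the same topology as binary
    occupancy matrices for the grid solvers.
    """

    ny: int
    nx: int
    h_cm: float
    A: np.ndarray = None                 # (ny, nx) bool node occupancy
    B: np.ndarray = None                 # (ny, nx, 9) bool segment indicators
    seg_a: list = field(default_factory=list)   # (x, y) endpoint 1
    seg_b: list = field(default_factory=list)   # (x, y) endpoint 2
    seg_len: list = field(default_factory=list)  # cm
    seg_R: list = field(default_factory=list)    # cm
    tips: list = field(default_factory=list)
    roots: np.ndarray = None             # (12, 2) int
    c_ref: float = 1.0                   # initial shoulder VEGF maximum
    radius_cm: float = R0_CM             # segment radius (no adaptation)
    next_branch_id: int = 0

    def __post_init__(self):
        if self.A is None:
            self.A = np.zeros((self.ny, self.nx), dtype=bool)
        if self.B is None:
            self.B = np.zeros((self.ny, self.nx, 9), dtype=bool)

    @property
    def n_segments(self) -> int:
        return len(self.seg_a)

    @property
    def active_tips(self) -> list:
        return [t for t in self.tips if t.active]

    def add_segment(self, a: tuple, b: tuple, radius: float = None) -> None:
        """Create segment a--b, updating A and B reciprocally."""
        if radius is None:
            radius = self.radius_cm
        ax, ay = a
        bx, by = b
        dx, dy = bx - ax, by - ay
        k = _direction_index(dx, dy)
        if self.B[ay, ax, k]:
            return  # segment already present
        self.B[ay, ax, k] = True
        self.B[by, bx, OPPOSITE[k]] = True
        self.A[ay, ax] = True
        self.A[by, bx] = True
        self.seg_a.append((ax, ay))
        self.seg_b.append((bx, by))
        self.seg_len.append(self.h_cm * float(np.sqrt(LEN2[k])))
        self.seg_R.append(radius)

    def copy(self) -> "VesselNetwork":
        net = VesselNetwork(
            ny=self.ny, nx=self.nx, h_cm=self.h_cm,
            A=self.A.copy(), B=self.B.copy(),
            seg_a=list(self.seg_a), seg_b=list(self.seg_b),
            seg_len=list(self.seg_len), seg_R=list(self.seg_R),
            tips=[Tip(t.x, t.y, t.age, t.branch_id, t.active) for t in self.tips],
            roots=None if self.roots is None else self.roots.copy(),
            c_ref=self.c_ref, radius_cm=self.radius_cm,
            next_branch_id=self.next_branch_id,
        )
        return net


def _direction_index(dx: int, dy: int) -> int:
    for k in range(1, 9):
        if OFFSETS[k, 0] == dx and OFFSETS[k, 1] == dy:
            return k
    raise ValueError(f"({dx}, {dy}) is not a nine-point move")


def init_network(
    domain: PlaqueDomain, c_ref: float, radius_cm: float = R0_CM
) -> VesselNetwork:
    """Fresh network: the 12 sprout seeds occupied, one tip on each."""
    net = VesselNetwork(
        ny=domain.ny, nx=domain.nx, h_cm=domain.h_cm,
        c_ref=c_ref, radius_cm=radius_cm,
    )
    net.roots = domain.sprout_seeds.copy()
    for i, (x, y) in enumerate(domain.sprout_seeds):
        net.A[y, x] = True
        net.tips.append(Tip(int(x), int(y), age=0, branch_id=i))
    net.next_branch_id = len(net.tips)
    return net


def motion_coefficients(
    c: np.ndarray,
    f: np.ndarray,
    at: tuple,
    coeffs: StepCoefficients,
    motion_gain: float = 1.0,
) -> np.ndarray:
    """Movement probabilities P0..P8 at one tip location.

    Raw directional coefficients combine an isotropic random-motility weight
    ``D_n`` with chemotaxis and haptotaxis biases from central differences of
    VEGF and ECM along each direction (diagonal differences carry the 1/l^2
    spacing factor).  Negative raw coefficients are clamped to zero, the
    stationary coefficient absorbs the remainder, and the nine values are
    normalized to sum to one.
    """
    x, y = at
    ny, nx = c.shape
    if not (1 <= x < nx - 1 and 1 <= y < ny - 1):
        raise TipBoundaryError(f"tip at ({x}, {y}) is on the boundary margin")
    chi_c = coeffs.chi_0 * coeffs.k_1 / (coeffs.k_1 + c[y, x])
    raw = np.zeros(9)
    for k in range(1, 9):
        dx, dy = OFFSETS[k]
        dc = c[y + dy, x + dx] - c[y - dy, x - dx]
        df = f[y + dy, x + dx] - f[y - dy, x - dx]
        raw[k] = motion_gain * (
            coeffs.D_n + (chi_c * dc + coeffs.rho_0 * df) / (2.0 * LEN2[k])
        )
    np.clip(raw, 0.0, None, out=raw)
    move_sum = raw[1:].sum()
    raw[0] = max(0.0, 1.0 - move_sum)
    total = raw.sum()
    if total <= 0.0:
        raw[0] = 1.0
        total = 1.0
    return raw / total


def move_tips(
    network: VesselNetwork,
    state: ChemicalState,
    rng: np.random.Generator,
    lumen: np.ndarray,
    coeffs: StepCoefficients,
    motion_gain: float = 1.0,
) -> int:
    """One movement step for every active tip, in randomized order.

    Each tip samples one of its nine outcomes from the cumulative
    distribution of its motion coefficients.  Moves into the lumen are
    blocked (the tip stays); moves create a segment and relocate the tip;
    tips reaching the boundary margin are retired.  Returns the number of
    segments added.
    """
    tips = network.active_tips
    if not tips:
        return 0
    order = rng.permutation(len(tips))
    ny, nx = network.A.shape
    added = 0
    for idx in order:
        tip = tips[idx]
        if not tip.active:
            continue
        if not (1 <= tip.x < nx - 1 and 1 <= tip.y < ny - 1):
            tip.active = False  # frozen at the boundary margin
            continue
        p = motion_coefficients(state.c, state.f, (tip.x, tip.y), coeffs, motion_gain)
        k = int(np.searchsorted(np.cumsum(p), rng.random(), side="right"))
        k = min(k, 8)
        if k == 0:
            continue
        dx, dy = OFFSETS[k]
        tx, ty = tip.x + dx, tip.y + dy
        if lumen[ty, tx]:
            continue  # blocked: tips never enter the lumen
        was_occupied = bool(network.A[ty, tx])
        before = network.n_segments
        network.add_segment((tip.x, tip.y), (tx, ty))
        added += network.n_segments - before
        tip.x, tip.y = tx, ty
        if was_occupied:
            tip.landed_on_occupied = True
    return added


def branch(
    network: VesselNetwork,
    c: np.ndarray,
    rng: np.random.Generator,
    cfg: BranchConfig,
    lumen: np.ndarray,
    coeffs: StepCoefficients,
    motion_gain: float = 1.0,
) -> int:
    """Tip branching driven by local VEGF.

    A tip of age >= ``cfg.age_gate`` with at least two free neighbour cells
    splits, with the tier probability of its local VEGF level, into two
    daughter tips placed on distinct free neighbours drawn proportionally to
    the motion coefficients.  Returns the number of branching events.
    """
    ny, nx = network.A.shape
    events = 0
    for tip in list(network.active_tips):
        if tip.age < cfg.age_gate or tip.landed_on_occupied:
            continue
        if not (1 <= tip.x < nx - 1 and 1 <= tip.y < ny - 1):
            continue
        free_ks = [
            k for k in range(1, 9)
            if not network.A[tip.y + OFFSETS[k, 1], tip.x + OFFSETS[k, 0]]
            and not lumen[tip.y + OFFSETS[k, 1], tip.x + OFFSETS[k, 0]]
        ]
        if len(free_ks) < 2:
            continue  # sufficient local space is requisite
        ratio = c[tip.y, tip.x] / network.c_ref if network.c_ref > 0 else 0.0
        if rng.random() >= cfg.probability(ratio):
            continue
        p = motion_coefficients(c, np.ones_like(c), (tip.x, tip.y), coeffs, motion_gain)
        w = np.array([p[k] for k in free_ks])
        if np.count_nonzero(w) < 2:  # degenerate bias: fall back to uniform
            w = np.ones(len(free_ks))
        w = w / w.sum()
        chosen = rng.choice(len(free_ks), size=2, replace=False, p=w)
        tip.active = False  # parent becomes a regular vessel node
        for j in chosen:
            k = free_ks[j]
            dx, dy = OFFSETS[k]
            cx, cy = tip.x + dx, tip.y + dy
            network.add_segment((tip.x, tip.y), (cx, cy))
            network.tips.append(
                Tip(cx, cy, age=0, branch_id=network.next_branch_id)
            )
            network.next_branch_id += 1
        events += 1
    return events


def anastomose(network: VesselNetwork) -> int:
    """Resolve tip fusions after a movement step.

    Tips sharing a cell fuse: the elder (ties broken by lower branch id)
    survives.  A lone tip that landed on a previously occupied node fuses
    into the vessel and is retired.  Returns the number of retired tips.
    """
    by_cell = {}
    for tip in network.active_tips:
        by_cell.setdefault((tip.x, tip.y), []).append(tip)
    retired = 0
    for cell, tips in by_cell.items():
        if len(tips) > 1:
            tips.sort(key=lambda t: (-t.age, t.branch_id))
            for loser in tips[1:]:
                loser.active = False
                retired += 1
            tips[0].landed_on_occupied = False
        else:
            tip = tips[0]
            if tip.landed_on_occupied:
                tip.active = False
                retired += 1
    for tip in network.tips:
        tip.landed_on_occupied = False
    return retired


@dataclass
class StageSnapshot:
    stage: int
    network: VesselNetwork
    chem: ChemicalState
    segments_added: int
    branch_events: int
    tips_active: int


@dataclass
class AngiogenesisHistory:
    snapshots: list
    termination_stage: int
    hit_cap: bool


def run_angiogenesis(
    domain: PlaqueDomain,
    chem: ChemicalState,
    coeffs: StepCoefficients,
    rng: np.random.Generator,
    branch_cfg: BranchConfig = BranchConfig(),
    stage_steps: int = 150,
    max_stages: int = 20,
    motion_gain: float = 1.0,
    radius_cm: float = R0_CM,
    step_hook=None,
    stage_hook=None,
) -> AngiogenesisHistory:
    """Grow the network stage by stage until sprout activity ceases.

    One stage is ``stage_steps`` simulation steps of chemical update + tip
    movement + branching + anastomosis.  A snapshot is recorded at the end of
    every stage; the run terminates at the first stage during which the
    vasculature stopped growing (no segment added, which implies no new
    sprout either), or at ``max_stages`` (flagged with ``hit_cap``).  ``step_hook(step, network, chem)`` and
    ``stage_hook(snapshot)`` allow the caller to interleave hemodynamic and
    hemorrhage updates.
    """
    c_ref = float(chem.c[domain.region_mask(Region.SA)].max())
    network = init_network(domain, c_ref=c_ref, radius_cm=radius_cm)
    lumen = domain.region_mask(Region.LUMEN)
    snapshots = []
    hit_cap = False
    stage = 0
    while True:
        stage += 1
        added = branches = 0
        for step in range(stage_steps):
            step_fields(chem, network.A, coeffs, dt=1.0)
            added += move_tips(network, chem, rng, lumen, coeffs, motion_gain)
            branches += branch(network, chem.c, rng, branch_cfg, lumen, coeffs, motion_gain)
            anastomose(network)
            for tip in network.active_tips:
                tip.age += 1
            if step_hook is not None:
                step_hook(step, network, chem)
        snap = StageSnapshot(
            stage=stage,
            network=network.copy(),
            chem=chem.copy(),
            segments_added=added,
            branch_events=branches,
            tips_active=len(network.active_tips),
        )
        snapshots.append(snap)
        if stage_hook is not None:
            stage_hook(snap)
        if added == 0:
            break
        if stage >= max_stages:
            hit_cap = True
            break
    return AngiogenesisHistory(
        snapshots=snapshots, termination_stage=stage, hit_cap=hit_cap
    )
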