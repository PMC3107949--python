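"""Quasi-static equilibrium of the skeleton by penalized energy minimization.

The solved state minimizes a total potential

* tension-only spring energy ``0.5 k max(0, L - L0)^2`` per ligament band;
* unilateral penalty energy ``kp/(e+1) * pen^(e+1)`` for ground contacts
  (sphere below the ground plane) and joint contacts (point pair closer
  than its frozen rest gap);
* a tangential ground spring anchored at each contact's neutral position
  (quasi-static no-slip regularization: a frictionless plane could not
  equilibrate the Achilles couple);
* load work terms: an axial force applied downward at the proximal tibia,
  and the Achilles tendon as a constant-tension cable from the calcaneal
  tuberosity to a proximal gastrocnemius/soleus point.

Generalized coordinates: the fusion group containing the tibia unit is
restrained to one coordinate (superior-inferior translation); every other
fusion group carries 3 translations (mm) + 3 rotation coordinates
(rotation vector about the group centroid, scaled by a characteristic
length so all coordinates are in mm and the gradient is in N).

Loads are ramped in equal increments with warm starts (tension-only
networks switch slack/taut; continuation avoids spurious minima); each
stage is minimized with L-BFGS-B using the analytic gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .anatomy import Skeleton, JointContactPair
from .geometry import Pose, rotvec_to_matrix, so3_left_jacobian
from .ligaments import LigamentBand

__all__ = [
    "LoadCase",
    "ContactSet",
    "SolverOptions",
    "DofLayout",
    "EquilibriumResult",
    "degrees_of_freedom",
    "build_contact_set",
    "System",
    "total_potential",
    "solve_equilibrium",
    "ground_region_loads",
    "joint_contact_force",
]

GROUND_REGIONS = ("ray1", "ray2", "ray3", "ray4", "ray5", "calcaneus")


@dataclass(frozen=True)
class LoadCase:
    """Mid-stance load set (N)."""

    axial_load_N: float = 690.0
    achilles_load_N: float = 345.0
    axial_landmark: tuple[str, str] = ("tibfib", "tibia_proximal")
    achilles_insertion: tuple[str, str] = ("calcaneus", "achilles_insertion")
    achilles_origin: tuple[str, str] = ("tibfib", "gastroc_proximal")

    def __post_init__(self):
        if self.axial_load_N < 0 or self.achilles_load_N < 0:
            raise ValueError("loads must be non-negative")

    def scaled(self, f: float) -> "LoadCase":
        return LoadCase(
            self.axial_load_N * f,
            self.achilles_load_N * f,
            self.axial_landmark,
            self.achilles_insertion,
            self.achilles_origin,
        )


@dataclass
class ContactSet:
    """Ground contacts + joint contact pairs + penalty law."""

    ground: list  # [(bone_name, GroundContact)]
    joints: list[JointContactPair]
    penalty_stiffness: float = 2000.0  # N/mm
    penalty_exponent: float = 1.0

    def __post_init__(self):
        if self.penalty_stiffness <= 0:
            raise ValueError("penalty stiffness must be > 0")


def build_contact_set(
    skeleton: Skeleton,
    penalty_stiffness: float = 2000.0,
    penalty_exponent: float = 1.0,
) -> ContactSet:
    """Collect skeleton contacts; joint pairs inside one fusion group are
    dropped (a fused joint transmits load through the fusion constraint)."""
    ground = [(b.name, c) for b in skeleton.bones.values() for c in b.contact_points]
    fg = {name: bone.fusion_group for name, bone in skeleton.bones.items()}
    joints = [p for p in skeleton.joint_pairs if fg[p.bone_a] != fg[p.bone_b]]
    return ContactSet(ground, joints, penalty_stiffness, penalty_exponent)


@dataclass(frozen=True)
class SolverOptions:
    tolerance_N: float = 0.5  # on the scaled gradient norm (force units)
    max_iter_per_stage: int = 800
    n_ramp_stages: int = 10
    penalty_stiffness: float = 2000.0  # N/mm
    penalty_exponent: float = 1.0
    tangential_stiffness: float = 40.0  # N/mm, ground tangential spring
    rotation_scale_mm: float = 50.0  # rotation coordinate = rotvec * scale
    # trust-region continuation: each ramp stage is minimized inside a box
    # of this half-width (mm) around the previous solution, re-centering
    # until the minimizer is interior. Unilateral networks buckle through
    # unphysical basins if the minimizer is allowed arbitrary steps; the
    # box is inactive at any accepted solution, so it never alters the
    # converged physics.
    trust_radius_mm: float = 4.0
    max_recenter: int = 25


@dataclass
class DofLayout:
    """Generalized-coordinate layout over fusion groups."""

    groups: list[str]
    slices: dict[str, slice]
    n_coords: int
    tibia_group: str
    group_of_bone: dict[str, str]
    centers: dict[str, np.ndarray]  # rotation centers (reference centroid)


def degrees_of_freedom(skeleton: Skeleton) -> DofLayout:
    """Coordinate layout: tibia group 1 coordinate, every other group 6."""
    group_of_bone = {n: b.fusion_group for n, b in skeleton.bones.items()}
    groups: list[str] = []
    for name in skeleton.bones:  # preserve bone order
        g = group_of_bone[name]
        if g not in groups:
            groups.append(g)
    tibia_group = group_of_bone["tibfib"]
    slices = {}
    pos = 0
    for g in groups:
        width = 1 if g == tibia_group else 6
        slices[g] = slice(pos, pos + width)
        pos += width
    centers = {}
    for g in groups:
        members = [b for b in skeleton.bones.values() if b.fusion_group == g]
        centers[g] = np.mean([b.reference_pose.position for b in members], axis=0)
    return DofLayout(groups, slices, pos, tibia_group, group_of_bone, centers)


@dataclass
class EquilibriumResult:
    poses: dict[str, Pose]
    band_tensions: dict[str, float]  # N
    ground_forces: list  # (bone, contact name, region, force 3-vector N)
    joint_forces: list  # (joint, bone_a, bone_b, force on b, 3-vector N)
    gradient_norm: float
    converged: bool
    iterations: int
    energy_trace: list
    q: np.ndarray
    load_scale: float = 1.0
    load_case: LoadCase | None = None

    def to_dict(self) -> dict:
        return {
            "converged": bool(self.converged),
            "gradient_norm_N": float(self.gradient_norm),
            "iterations": int(self.iterations),
            "load_scale": float(self.load_scale),
            "poses": {k: p.to_dict() for k, p in self.poses.items()},
            "band_tensions_N": {k: float(v) for k, v in self.band_tensions.items()},
            "ground_forces": [
                {"bone": b, "contact": c, "region": r, "force_N": [float(x) for x in f]}
                for (b, c, r, f) in self.ground_forces
            ],
            "joint_forces": [
                {"joint": j, "bone_a": a, "bone_b": b, "force_on_b_N": [float(x) for x in f]}
                for (j, a, b, f) in self.joint_forces
            ],
        }


class System:
    """Precompiled energy/gradient evaluator for one scenario."""

    def __init__(
        self,
        skeleton: Skeleton,
        bands: list[LigamentBand],
        load_case: LoadCase | None = None,
        contacts: ContactSet | None = None,
        options: SolverOptions | None = None,
        tangential_anchors: np.ndarray | None = None,
    ):
        self.skeleton = skeleton
        self.bands = list(bands)
        self.options = options if options is not None else SolverOptions()
        self.load_case = load_case if load_case is not None else LoadCase()
        self.contacts = (
            contacts
            if contacts is not None
            else build_contact_set(
                skeleton, self.options.penalty_stiffness, self.options.penalty_exponent
            )
        )
        self.layout = degrees_of_freedom(skeleton)
        self._compile()
        if tangential_anchors is not None:
            anchors = np.asarray(tangential_anchors, dtype=float)
            if anchors.shape != self.ground_anchor.shape:
                raise ValueError("tangential anchor array shape mismatch")
            self.ground_anchor = anchors.copy()

    # ------------------------------------------------------------------ #

    def _compile(self) -> None:
        lay = self.layout
        group_index = {g: i for i, g in enumerate(lay.groups)}
        ref_poses = self.skeleton.reference_poses()

        pts: list[np.ndarray] = []
        pt_group: list[int] = []
        cache: dict[tuple[str, str], int] = {}

        def add_point(bone: str, landmark: str) -> int:
            key = (bone, landmark)
            if key in cache:
                return cache[key]
            w = self.skeleton.world_landmark(bone, landmark, poses=ref_poses)
            idx = len(pts)
            pts.append(w)
            pt_group.append(group_index[lay.group_of_bone[bone]])
            cache[key] = idx
            return idx

        # ligament band segments
        seg_i, seg_j, seg_band = [], [], []
        for bi, band in enumerate(self.bands):
            chain = [band.origin] + [(b, lm) for (b, lm, _r) in band.via_beads] + [band.insertion]
            ids = [add_point(b, lm) for (b, lm) in chain]
            for a, c in zip(ids[:-1], ids[1:]):
                seg_i.append(a)
                seg_j.append(c)
                seg_band.append(bi)
        self.seg_i = np.array(seg_i, dtype=int)
        self.seg_j = np.array(seg_j, dtype=int)
        self.seg_band = np.array(seg_band, dtype=int)
        self.band_k = np.array([b.stiffness_k for b in self.bands])
        self.band_L0 = np.array([b.rest_length_L0 for b in self.bands])

        # ground contacts (sphere centers are registered as pseudo-points)
        gidx, grad_r, gregion, gbone, gname = [], [], [], [], []
        for bone_name, c in self.contacts.ground:
            w = ref_poses[bone_name].transform(c.local)
            idx = len(pts)
            pts.append(w)
            pt_group.append(group_index[lay.group_of_bone[bone_name]])
            gidx.append(idx)
            grad_r.append(c.radius)
            gregion.append(c.region)
            gbone.append(bone_name)
            gname.append(c.name)
        self.ground_idx = np.array(gidx, dtype=int)
        self.ground_radius = np.array(grad_r)
        self.ground_region = gregion
        self.ground_bone = gbone
        self.ground_name = gname

        # joint contacts: facet pads (normal fixed in bone a via a tip
        # landmark) and ball centers (central compression-only element)
        facets = [p for p in self.contacts.joints if p.kind == "facet"]
        balls = [p for p in self.contacts.joints if p.kind == "ball"]
        self.joint_a = np.array([add_point(p.bone_a, p.landmark_a) for p in facets], dtype=int)
        self.joint_b = np.array([add_point(p.bone_b, p.landmark_b) for p in facets], dtype=int)
        self.joint_n = np.array([add_point(p.bone_a, p.landmark_n) for p in facets], dtype=int)
        self.joint_gap = np.array([p.rest_gap_mm for p in facets])
        self.ball_a = np.array([add_point(p.bone_a, p.landmark_a) for p in balls], dtype=int)
        self.ball_b = np.array([add_point(p.bone_b, p.landmark_b) for p in balls], dtype=int)
        self.ball_gap = np.array([p.rest_gap_mm for p in balls])
        self.joint_meta = [(p.joint, p.bone_a, p.bone_b) for p in facets] + [
            (p.joint, p.bone_a, p.bone_b) for p in balls
        ]

        # load application points
        lc = self.load_case
        self.axial_pt = add_point(*lc.axial_landmark)
        self.ach_ins_pt = add_point(*lc.achilles_insertion)
        self.ach_org_pt = add_point(*lc.achilles_origin)

        self.pts_ref = np.array(pts)
        self.pt_group = np.array(pt_group, dtype=int)
        self.n_pts = len(pts)
        # anchors for tangential ground springs: neutral world x/z
        self.ground_anchor = self.pts_ref[self.ground_idx][:, [0, 2]].copy()

        self.group_pts = [np.where(self.pt_group == i)[0] for i in range(len(lay.groups))]
        self.ref_y_axial = self.pts_ref[self.axial_pt][1]

    # ------------------------------------------------------------------ #

    def world_points(self, q: np.ndarray) -> np.ndarray:
        """All registered points in the world frame for coordinates ``q``."""
        lay = self.layout
        s = self.options.rotation_scale_mm
        P = np.empty_like(self.pts_ref)
        for gi, g in enumerate(lay.groups):
            idx = self.group_pts[gi]
            sl = lay.slices[g]
            c = lay.centers[g]
            if g == lay.tibia_group:
                P[idx] = self.pts_ref[idx] + np.array([0.0, q[sl][0], 0.0])
            else:
                t = q[sl][:3]
                R = rotvec_to_matrix(q[sl][3:] / s)
                P[idx] = (self.pts_ref[idx] - c) @ R.T + c + t
        return P

    def poses_from_q(self, q: np.ndarray) -> dict[str, Pose]:
        lay = self.layout
        s = self.options.rotation_scale_mm
        poses = {}
        for name, bone in self.skeleton.bones.items():
            g = lay.group_of_bone[name]
            sl = lay.slices[g]
            ref = bone.reference_pose
            if g == lay.tibia_group:
                poses[name] = Pose(ref.position + np.array([0.0, q[sl][0], 0.0]), ref.rotation.copy())
            else:
                c = lay.centers[g]
                t = q[sl][:3]
                R = rotvec_to_matrix(q[sl][3:] / s)
                poses[name] = Pose(R @ (ref.position - c) + c + t, R @ ref.rotation)
        return poses

    # ------------------------------------------------------------------ #

    def energy_grad(self, q: np.ndarray, load_scale: float = 1.0):
        """Total potential (N*mm) and analytic gradient (N) at ``q``."""
        if not np.all(np.isfinite(q)):
            raise FloatingPointError("non-finite state passed to energy evaluation")
        opts = self.options
        P = self.world_points(q)
        G = np.zeros_like(P)  # dE/dP per point
        E = 0.0

        # --- ligament springs ------------------------------------------ #
        d = P[self.seg_j] - P[self.seg_i]
        seg_len = np.linalg.norm(d, axis=1)
        L = np.zeros(len(self.bands))
        np.add.at(L, self.seg_band, seg_len)
        elong = np.maximum(0.0, L - self.band_L0)
        T = self.band_k * elong
        E += 0.5 * float(np.dot(T, elong))
        u = d / np.maximum(seg_len, 1e-12)[:, None]
        Tu = T[self.seg_band][:, None] * u
        np.add.at(G, self.seg_i, -Tu)
        np.add.at(G, self.seg_j, Tu)
        self._last_band_lengths = L
        self._last_band_tensions = T

        # --- ground contacts ------------------------------------------- #
        kp, e = self.contacts.penalty_stiffness, self.contacts.penalty_exponent
        C = P[self.ground_idx]
        pen = (self.skeleton.ground_height + self.ground_radius) - C[:, 1]
        active = pen > 0.0
        pen_a = np.where(active, pen, 0.0)
        E += kp / (e + 1.0) * float(np.sum(pen_a ** (e + 1.0)))
        fn = kp * pen_a**e * active  # upward normal force magnitude
        G[self.ground_idx, 1] -= fn
        # tangential no-slip spring (always engaged; contacts start touching)
        kt = opts.tangential_stiffness
        dt = C[:, [0, 2]] - self.ground_anchor
        E += 0.5 * kt * float(np.sum(dt**2))
        G[self.ground_idx, 0] += kt * dt[:, 0]
        G[self.ground_idx, 2] += kt * dt[:, 1]
        self._last_ground_normal = fn
        self._last_ground_tangential = -kt * dt  # force on the bone

        # --- joint contacts --------------------------------------------- #
        joint_forces = []
        if len(self.joint_a):
            Pa, Pb, Pn = P[self.joint_a], P[self.joint_b], P[self.joint_n]
            nvec = Pn - Pa  # unit by rigid-body construction
            rel = Pb - Pa
            g = np.einsum("ij,ij->i", rel, nvec)  # normal gap
            penj = self.joint_gap - g
            actj = penj > 0.0
            penj_a = np.where(actj, penj, 0.0)
            E += kp / (e + 1.0) * float(np.sum(penj_a ** (e + 1.0)))
            fj = kp * penj_a**e * actj  # dE/dg = -fj
            # dg/dPb = n, dg/dPn = rel, dg/dPa = -(n + rel)
            np.add.at(G, self.joint_b, -fj[:, None] * nvec)
            np.add.at(G, self.joint_n, -fj[:, None] * rel)
            np.add.at(G, self.joint_a, fj[:, None] * (nvec + rel))
            joint_forces.append(fj[:, None] * nvec)  # force exerted on bone b
        if len(self.ball_a):
            db = P[self.ball_b] - P[self.ball_a]
            dist = np.linalg.norm(db, axis=1)
            penb = self.ball_gap - dist
            actb = penb > 0.0
            penb_a = np.where(actb, penb, 0.0)
            E += kp / (e + 1.0) * float(np.sum(penb_a ** (e + 1.0)))
            fb = kp * penb_a**e * actb
            ub = db / np.maximum(dist, 1e-12)[:, None]
            Fb = fb[:, None] * ub  # force exerted on bone b (push apart)
            np.add.at(G, self.ball_b, -Fb)
            np.add.at(G, self.ball_a, Fb)
            joint_forces.append(Fb)
        self._last_joint_force = (
            np.concatenate(joint_forces) if joint_forces else np.zeros((0, 3))
        )

        # --- applied loads ---------------------------------------------- #
        axial = self.load_case.axial_load_N * load_scale
        E += axial * (P[self.axial_pt][1] - self.ref_y_axial)
        G[self.axial_pt, 1] += axial

        ach = self.load_case.achilles_load_N * load_scale
        if ach > 0.0:
            cab = P[self.ach_org_pt] - P[self.ach_ins_pt]
            clen = np.linalg.norm(cab)
            E += ach * clen
            ucab = cab / max(clen, 1e-12)
            G[self.ach_ins_pt] -= ach * ucab
            G[self.ach_org_pt] += ach * ucab

        # --- map point gradients to generalized coordinates -------------- #
        lay = self.layout
        s = opts.rotation_scale_mm
        grad = np.zeros_like(q)
        for gi, g in enumerate(lay.groups):
            idx = self.group_pts[gi]
            sl = lay.slices[g]
            Gp = G[idx]
            if g == lay.tibia_group:
                grad[sl.start] = Gp[:, 1].sum()
            else:
                c = lay.centers[g]
                t = q[sl][:3]
                grad[sl][:3] = Gp.sum(axis=0)
                arms = P[idx] - (c + t)
                Gr = np.cross(arms, Gp).sum(axis=0)
                Jl = so3_left_jacobian(q[sl][3:] / s)
                grad[sl][3:] = (Jl.T @ Gr) / s
        return E, grad

    def gradient_norm(self, q: np.ndarray, load_scale: float = 1.0) -> float:
        return float(np.linalg.norm(self.energy_grad(q, load_scale)[1]))


def total_potential(state: np.ndarray, system: System, load_scale: float = 1.0) -> float:
    """Total potential energy (N*mm) at generalized coordinates ``state``."""
    return system.energy_grad(np.asarray(state, dtype=float), load_scale)[0]


def solve_equilibrium(
    skeleton: Skeleton,
    bands: list[LigamentBand],
    load_case: LoadCase | None = None,
    contacts: ContactSet | None = None,
    options: SolverOptions | None = None,
    warm_start: np.ndarray | None = None,
    tangential_anchors: np.ndarray | None = None,
) -> EquilibriumResult:
    """Ramped, warm-started minimization of the total potential.

    ``tangential_anchors`` fixes the ground no-slip spring anchors (world
    x/z per ground contact, as returned by :func:`ground_anchor_positions`);
    by default anchors sit at the reference-pose contact positions.
    Non-convergence returns a result flagged ``converged=False``; a
    non-finite state raises naming the ramp stage.
    """
    options = options if options is not None else SolverOptions()
    system = System(skeleton, bands, load_case, contacts, options, tangential_anchors)
    q = (
        np.zeros(system.layout.n_coords)
        if warm_start is None
        else np.array(warm_start, dtype=float)
    )

    trace: list = []
    iterations = 0
    n = max(1, options.n_ramp_stages)
    lc = system.load_case
    has_load = (lc.axial_load_N > 0.0) or (lc.achilles_load_N > 0.0)
    scales = [i / n for i in range(1, n + 1)] if has_load else [1.0]

    delta = options.trust_radius_mm
    for stage, lam in enumerate(scales):
        stage_trace: list = []
        last: dict = {"x": None, "E": None}

        def fun(x, _lam=lam, _last=last):
            E, g = system.energy_grad(x, _lam)
            _last["x"], _last["E"] = x.copy(), E
            return E, g

        def cb(xk, _lam=lam, _tr=stage_trace, _last=last):
            if _last["x"] is not None and np.array_equal(_last["x"], xk):
                _tr.append(_last["E"])
            else:
                _tr.append(system.energy_grad(xk, _lam)[0])

        for _round in range(options.max_recenter):
            bounds = list(zip(q - delta, q + delta))
            res = minimize(
                fun,
                q,
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                callback=cb,
                options={
                    "maxiter": options.max_iter_per_stage,
                    "ftol": 1e-15,
                    "gtol": options.tolerance_N / 20.0,
                    "maxcor": 30,
                },
            )
            q_prev = q
            q = res.x
            iterations += int(res.nit)
            if not np.all(np.isfinite(q)):
                raise FloatingPointError(
                    f"non-finite state after ramp stage {stage + 1}/{len(scales)}"
                )
            at_bound = np.abs(q - q_prev) >= delta * (1.0 - 1e-9)
            gnorm_stage = float(np.linalg.norm(system.energy_grad(q, lam)[1]))
            if not at_bound.any() and gnorm_stage <= options.tolerance_N:
                break
            if not at_bound.any() and int(res.nit) == 0:
                break  # stalled interior; accept stage result as-is
        trace.append(stage_trace)

    E, g = system.energy_grad(q, scales[-1])
    gnorm = float(np.linalg.norm(g))
    converged = gnorm <= options.tolerance_N

    poses = system.poses_from_q(q)
    band_tensions = {
        b.name: float(t) for b, t in zip(system.bands, system._last_band_tensions)
    }
    ground_forces = []
    for k in range(len(system.ground_idx)):
        f = np.array(
            [
                system._last_ground_tangential[k, 0],
                system._last_ground_normal[k],
                system._last_ground_tangential[k, 1],
            ]
        )
        ground_forces.append((system.ground_bone[k], system.ground_name[k], system.ground_region[k], f))
    joint_forces = [
        (joint, a, b, system._last_joint_force[k])  # force exerted on bone b
        for k, (joint, a, b) in enumerate(system.joint_meta)
    ]

    return EquilibriumResult(
        poses=poses,
        band_tensions=band_tensions,
        ground_forces=ground_forces,
        joint_forces=joint_forces,
        gradient_norm=gnorm,
        converged=converged,
        iterations=iterations,
        energy_trace=trace,
        q=q,
        load_scale=scales[-1],
        load_case=system.load_case,
    )


def ground_anchor_positions(
    skeleton: Skeleton, poses: dict[str, Pose], contacts: ContactSet | None = None
) -> np.ndarray:
    """World x/z of every ground contact center under ``poses``.

    Used to anchor the tangential no-slip springs where the foot first
    bears on the ground (the unloaded equilibrium pose).
    """
    contacts = contacts if contacts is not None else build_contact_set(skeleton)
    out = []
    for bone_name, c in contacts.ground:
        w = poses[bone_name].transform(c.local)
        out.append([w[0], w[2]])
    return np.array(out)


def solve_scenario_pair(
    skeleton: Skeleton,
    bands: list[LigamentBand],
    load_case: LoadCase | None = None,
    options: SolverOptions | None = None,
) -> tuple[EquilibriumResult, EquilibriumResult]:
    """Unloaded reference equilibrium + loaded equilibrium of one scenario.

    The unloaded state is solved free of tangential ground springs (a foot
    off load can re-pose freely — this is where an osteotomy re-shapes the
    foot); the loaded solve then anchors the no-slip springs at the
    unloaded contact positions and ramps the loads, warm-started from the
    unloaded solution.
    """
    from dataclasses import replace as _replace

    options = options if options is not None else SolverOptions()
    unloaded_opts = _replace(options, tangential_stiffness=0.0)
    r0 = solve_equilibrium(
        skeleton, bands, LoadCase(0.0, 0.0), options=unloaded_opts
    )
    anchors = ground_anchor_positions(skeleton, r0.poses)
    r1 = solve_equilibrium(
        skeleton,
        bands,
        load_case,
        options=options,
        warm_start=r0.q,
        tangential_anchors=anchors,
    )
    return r0, r1


def ground_region_loads(result: EquilibriumResult) -> dict[str, float]:
    """Vertical plantar load per region (N), from a converged result."""
    if not result.converged:
        raise ValueError("ground_region_loads requires a converged equilibrium")
    loads = {r: 0.0 for r in GROUND_REGIONS}
    for _bone, _name, region, f in result.ground_forces:
        loads.setdefault(region, 0.0)
        loads[region] += float(f[1])
    return loads


def joint_contact_force(result: EquilibriumResult, bone_a: str, bone_b: str) -> float:
    """Resultant contact-force magnitude (N) across a declared bone pair."""
    if not result.converged:
        raise ValueError("joint_contact_force requires a converged equilibrium")
    pair = {bone_a, bone_b}
    forces = [f for (j, a, b, f) in result.joint_forces if {a, b} == pair]
    if not forces:
        raise KeyError(f"no declared joint contacts between {bone_a!r} and {bone_b!r}")
    return float(np.linalg.norm(np.sum(forces, axis=0)))
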