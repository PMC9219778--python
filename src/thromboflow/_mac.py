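"""Coupled staggered-grid (MAC) finite-volume system for steady 2D flow.

Discretizes steady incompressible momentum + continuity on a marker-and-cell
layout: u on vertical faces ``(ny, nx+1)``, v on horizontal faces
``(ny+1, nx)``, pressure at cell centers.  Convection is first-order upwind
with Picard (Oseen) linearization; diffusion is central with a
variable-viscosity Laplacian; the clot momentum sink enters as a
velocity-proportional (Brinkman) diagonal term, or as a constant-magnitude
drag opposing the previous iterate when ``sink_form="constant"``.

The solver supports inlet cells only in column 0 and outlet cells only in
column nx-1 (walls anywhere); this covers every built-in geometry and keeps
open-boundary bookkeeping simple.  No-slip staircase walls use half-cell
Dirichlet values for the tangential velocity, which recovers second-order
plane-Poiseuille profiles on wall-aligned grids.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .errors import GeometryError
from .grid import CellKind, StructuredGrid2D

UNK, DIR, ALIAS, WALLTAN = 0, 1, 2, 3

_W = int(CellKind.WALL)
_F = int(CellKind.FLUID)
_I = int(CellKind.INLET)
_O = int(CellKind.OUTLET)


def _extended_kind(grid: StructuredGrid2D) -> np.ndarray:
    """Cell kinds padded with one ring of WALL (outside the domain)."""
    ny, nx = grid.ny, grid.nx
    k = np.full((ny + 2, nx + 2), _W, dtype=np.int8)
    k[1:-1, 1:-1] = grid.cell_kind
    return k


class MacSystem:
    """Pre-indexed coupled momentum/continuity system on one grid.

    Parameters
    ----------
    grid : StructuredGrid2D
    inlet_mode : {"velocity", "pressure", None}
    uin : ndarray (ny,), inlet face velocity per row (velocity mode)
    p_in, p_out : float, boundary pressures (pressure mode / outlet)
    """

    def __init__(self, grid, inlet_mode=None, uin=None, p_in=0.0, p_out=0.0):
        self.grid = grid
        ny, nx = grid.ny, grid.nx
        kind = grid.cell_kind
        self.inlet_mode = inlet_mode
        self.p_in, self.p_out = float(p_in), float(p_out)

        has_inlet = bool(np.any(kind == _I))
        has_outlet = bool(np.any(kind == _O))
        if has_inlet:
            if inlet_mode not in ("velocity", "pressure"):
                raise GeometryError("grid has inlet cells but no inflow BC given")
            if np.any((kind == _I) & (np.arange(nx)[None, :] != 0)):
                raise GeometryError("solver requires inlet cells in column 0 only")
        if has_outlet and np.any((kind == _O) & (np.arange(nx)[None, :] != nx - 1)):
            raise GeometryError("solver requires outlet cells in column nx-1 only")
        if has_inlet and inlet_mode == "velocity" and not has_outlet:
            raise GeometryError("velocity-driven inlet requires an outlet")
        self.sealed = not (has_outlet or (has_inlet and inlet_mode == "pressure"))

        ke = _extended_kind(grid)  # ke[j+1, i+1] == kind[j, i]

        # ---- face classification -------------------------------------
        self.Ucl = np.full((ny, nx + 1), DIR, dtype=np.int8)
        self.Uval = np.zeros((ny, nx + 1))
        self.Vcl = np.full((ny + 1, nx), DIR, dtype=np.int8)
        L = ke[1:-1, :-1]  # cell left of U face (ny, nx+1)
        R = ke[1:-1, 1:]
        open_lr = np.isin(L, (_F, _I, _O)) & np.isin(R, (_F, _I, _O))
        self.Ucl[open_lr & (L == _F) & (R == _F)] = UNK
        self.Ucl[open_lr & (L == _F) & (R == _O)] = UNK
        inlet_rows = kind[:, 0] == _I
        if has_inlet:
            if inlet_mode == "velocity":
                if uin is None:
                    raise GeometryError("velocity inlet requires uin profile")
                for I in (0, 1):
                    self.Ucl[inlet_rows, I] = DIR
                    self.Uval[inlet_rows, I] = uin[inlet_rows]
            else:
                self.Ucl[inlet_rows, 0] = ALIAS
                self.Ucl[inlet_rows & (kind[:, 1] == _F), 1] = UNK
        outlet_rows = kind[:, -1] == _O
        if has_outlet:
            self.Ucl[outlet_rows, nx] = ALIAS

        B = ke[:-1, 1:-1]  # cell below V face (ny+1, nx)
        T = ke[1:, 1:-1]
        self.Vcl[(B == _F) & (T == _F)] = UNK
        self.v_alias = (B == _O) & (T == _O)  # lateral zero-gradient copy
        self.Vcl[self.v_alias] = ALIAS

        # ---- unknown indexing ----------------------------------------
        self.u_unk = np.argwhere(self.Ucl == UNK)  # (nU, 2) -> (j, I)
        self.v_unk = np.argwhere(self.Vcl == UNK)  # (nV, 2) -> (J, i)
        self.nU = len(self.u_unk)
        self.nV = len(self.v_unk)
        self.Uidx = np.full((ny, nx + 1), -1, dtype=np.int64)
        self.Uidx[self.Ucl == UNK] = np.arange(self.nU)
        self.Vidx = np.full((ny + 1, nx), -1, dtype=np.int64)
        self.Vidx[self.Vcl == UNK] = np.arange(self.nV)
        fluid = grid.fluid
        self.p_cells = np.argwhere(fluid)
        self.nP = len(self.p_cells)
        self.Pidx = np.full((ny, nx), -1, dtype=np.int64)
        self.Pidx[fluid] = np.arange(self.nP)
        self.n = self.nU + self.nV + self.nP
        self.pin_pressure = self.sealed

        self._index_u_neighbors(ke)
        self._index_v_neighbors(ke)
        self._index_continuity()

    # -----------------------------------------------------------------
    def _nb_info_u(self, ke, j, I, dj, dI):
        """Classify the (dj, dI) neighbor U face of unknown U face (j, I)."""
        grid = self.grid
        ny, nx = grid.ny, grid.nx
        jn, In = j + dj, I + dI
        if dj != 0:
            # cells beside the neighbor face, in extended coordinates
            c1 = ke[jn + 1, In]      # (jn, In-1)
            c2 = ke[jn + 1, In + 1]  # (jn, In)
            if c1 == _W and c2 == _W:
                wu = 0.0
                cnt = 0
                for ii in (In - 1, In):
                    if 0 <= jn < ny and 0 <= ii < nx and grid.cell_kind[jn, ii] == _W:
                        wu += grid.wall_u[jn, ii]
                        cnt += 1
                return WALLTAN, -1, (wu / cnt if cnt else 0.0), 2.0
        if 0 <= jn < ny and 0 <= In <= nx:
            cl = self.Ucl[jn, In]
            if cl == UNK:
                return UNK, self.Uidx[jn, In], 0.0, 1.0
            if cl == ALIAS:
                return ALIAS, -1, 0.0, 1.0
            return DIR, -1, self.Uval[jn, In], 1.0
        return DIR, -1, 0.0, 1.0

    def _nb_info_v(self, ke, J, i, dJ, di):
        grid = self.grid
        ny, nx = grid.ny, grid.nx
        Jn, inn = J + dJ, i + di
        if di != 0:
            c1 = ke[Jn, inn + 1]      # (Jn-1, inn)
            c2 = ke[Jn + 1, inn + 1]  # (Jn, inn)
            if c1 == _W and c2 == _W:
                # tangential wall for v: walls move only in x -> value 0
                return WALLTAN, -1, 0.0, 2.0
        if 0 <= Jn <= ny and 0 <= inn < nx:
            cl = self.Vcl[Jn, inn]
            if cl == UNK:
                return UNK, self.Vidx[Jn, inn], 0.0, 1.0
            if cl == ALIAS:
                return ALIAS, -1, 0.0, 1.0
            return DIR, -1, 0.0, 1.0
        return DIR, -1, 0.0, 1.0

    def _index_u_neighbors(self, ke):
        dirs = {"E": (0, 1), "W": (0, -1), "N": (1, 0), "S": (-1, 0)}
        nU = self.nU
        self.u_nb = {}
        for name, (dj, dI) in dirs.items():
            code = np.empty(nU, dtype=np.int8)
            col = np.empty(nU, dtype=np.int64)
            val = np.empty(nU)
            dist = np.empty(nU)
            for k, (j, I) in enumerate(self.u_unk):
                code[k], col[k], val[k], dist[k] = self._nb_info_u(ke, j, I, dj, dI)
            self.u_nb[name] = (code, col, val, dist)
        # pressure neighbors: left cell (j, I-1), right cell (j, I)
        kind = self.grid.cell_kind
        self.u_pL = np.empty(nU, dtype=np.int64)
        self.u_pR = np.empty(nU, dtype=np.int64)
        self.u_pLval = np.zeros(nU)
        self.u_pRval = np.zeros(nU)
        for k, (j, I) in enumerate(self.u_unk):
            for side, i_cell in (("L", I - 1), ("R", I)):
                kd = kind[j, i_cell]
                if kd == _F:
                    idx = self.Pidx[j, i_cell]
                    vv = 0.0
                elif kd == _I:
                    idx, vv = -1, self.p_in
                elif kd == _O:
                    idx, vv = -1, self.p_out
                else:  # pragma: no cover - excluded by classification
                    raise GeometryError("wall pressure neighbor of unknown face")
                if side == "L":
                    self.u_pL[k], self.u_pLval[k] = idx, vv
                else:
                    self.u_pR[k], self.u_pRval[k] = idx, vv

    def _index_v_neighbors(self, ke):
        dirs = {"E": (0, 1), "W": (0, -1), "N": (1, 0), "S": (-1, 0)}
        nV = self.nV
        self.v_nb = {}
        for name, (dJ, di) in dirs.items():
            code = np.empty(nV, dtype=np.int8)
            col = np.empty(nV, dtype=np.int64)
            val = np.empty(nV)
            dist = np.empty(nV)
            for k, (J, i) in enumerate(self.v_unk):
                code[k], col[k], val[k], dist[k] = self._nb_info_v(ke, J, i, dJ, di)
            self.v_nb[name] = (code, col, val, dist)
        self.v_pB = np.empty(nV, dtype=np.int64)
        self.v_pT = np.empty(nV, dtype=np.int64)
        for k, (J, i) in enumerate(self.v_unk):
            self.v_pB[k] = self.Pidx[J - 1, i]
            self.v_pT[k] = self.Pidx[J, i]
        if self.nV and (np.any(self.v_pB < 0) or np.any(self.v_pT < 0)):
            raise GeometryError("v-face with non-fluid pressure neighbor")

    def _index_continuity(self):
        """Record, per fluid cell, its four face indices and classes."""
        jj = self.p_cells[:, 0]
        ii = self.p_cells[:, 1]
        self.c_uW = self.Uidx[jj, ii]
        self.c_uE = self.Uidx[jj, ii + 1]
        self.c_vS = self.Vidx[jj, ii]
        self.c_vN = self.Vidx[jj + 1, ii]
        self.c_jj, self.c_ii = jj, ii

    # -----------------------------------------------------------------
    def fill_faces(self, U, V):
        """Impose Dirichlet/zero-gradient values on non-unknown faces."""
        U[self.Ucl == DIR] = self.Uval[self.Ucl == DIR]
        nx = self.grid.nx
        left_alias = self.Ucl[:, 0] == ALIAS
        U[left_alias, 0] = U[left_alias, 1]
        right_alias = self.Ucl[:, nx] == ALIAS
        U[right_alias, nx] = U[right_alias, nx - 1]
        V[self.Vcl == DIR] = 0.0
        if np.any(self.v_alias):
            J, i = np.nonzero(self.v_alias)
            V[J, i] = V[J, np.maximum(i - 1, 0)]
        return U, V

    def _mu_corner(self, mu_c, j_cells, i_cells):
        """Mean viscosity at the corner above-left of cell (j_cells, i_cells)."""
        ny, nx = self.grid.ny, self.grid.nx
        out = np.zeros(len(j_cells))
        for dj, di in ((0, 0), (0, -1), (-1, 0), (-1, -1)):
            jc = np.clip(j_cells + dj, 0, ny - 1)
            ic = np.clip(i_cells + di, 0, nx - 1)
            out += mu_c[jc, ic]
        return out / 4.0

    def coefficients(self, U, V, mu_c, phi_c, rho, k_M, sink_form):
        """Upwind/diffusion coefficients for the current Picard iterate.

        Returns a dict of per-unknown arrays used by both the matrix
        assembly and the nonlinear residual evaluation.
        """
        g = self.grid
        dx, dy = g.dx, g.dy
        co = {}
        # ---------------- u faces ------------------------------------
        if self.nU:
            j = self.u_unk[:, 0]
            I = self.u_unk[:, 1]
            Fe = 0.5 * (U[j, I] + U[j, I + 1]) * dy
            Fw = 0.5 * (U[j, I - 1] + U[j, I]) * dy
            Fn = 0.5 * (V[j + 1, I - 1] + V[j + 1, I]) * dx
            Fs = 0.5 * (V[j, I - 1] + V[j, I]) * dx
            mu_R = mu_c[j, np.minimum(I, g.nx - 1)]
            mu_L = mu_c[j, np.maximum(I - 1, 0)]
            mu_n = self._mu_corner(mu_c, j + 1, I)
            mu_s = self._mu_corner(mu_c, j, I)
            aE = rho * np.maximum(-Fe, 0.0) + mu_R * dy / dx
            aW = rho * np.maximum(Fw, 0.0) + mu_L * dy / dx
            aN = rho * np.maximum(-Fn, 0.0) + mu_n * dx / dy * self.u_nb["N"][3]
            aS = rho * np.maximum(Fs, 0.0) + mu_s * dx / dy * self.u_nb["S"][3]
            phi_f = 0.5 * (
                phi_c[j, np.maximum(I - 1, 0)] + phi_c[j, np.minimum(I, g.nx - 1)]
            )
            aP = aE + aW + aN + aS + rho * (Fe - Fw + Fn - Fs)
            bu = np.zeros(self.nU)
            if sink_form == "brinkman":
                aP = aP + k_M * phi_f * dx * dy
            else:  # constant-magnitude drag opposing the previous iterate
                uc = U[j, I]
                vc = 0.25 * (V[j, I - 1] + V[j, I] + V[j + 1, I - 1] + V[j + 1, I])
                speed = np.hypot(uc, vc)
                dirn = np.where(speed > 0, uc / np.maximum(speed, 1e-300), 0.0)
                bu -= k_M * phi_f * dx * dy * dirn
            co["u"] = dict(aE=aE, aW=aW, aN=aN, aS=aS, aP=aP, b=bu)
        # ---------------- v faces ------------------------------------
        if self.nV:
            J = self.v_unk[:, 0]
            i = self.v_unk[:, 1]
            Fe = 0.5 * (U[J - 1, i + 1] + U[J, i + 1]) * dy
            Fw = 0.5 * (U[J - 1, i] + U[J, i]) * dy
            Fn = 0.5 * (V[J, i] + V[J + 1, i]) * dx
            Fs = 0.5 * (V[J - 1, i] + V[J, i]) * dx
            mu_T = mu_c[np.minimum(J, g.ny - 1), i]
            mu_B = mu_c[np.maximum(J - 1, 0), i]
            mu_e = self._mu_corner(mu_c, J, i + 1)
            mu_w = self._mu_corner(mu_c, J, i)
            aN = rho * np.maximum(-Fn, 0.0) + mu_T * dx / dy
            aS = rho * np.maximum(Fs, 0.0) + mu_B * dx / dy
            aE = rho * np.maximum(-Fe, 0.0) + mu_e * dy / dx * self.v_nb["E"][3]
            aW = rho * np.maximum(Fw, 0.0) + mu_w * dy / dx * self.v_nb["W"][3]
            phi_f = 0.5 * (
                phi_c[np.maximum(J - 1, 0), i] + phi_c[np.minimum(J, g.ny - 1), i]
            )
            aP = aE + aW + aN + aS + rho * (Fe - Fw + Fn - Fs)
            bv = np.zeros(self.nV)
            if sink_form == "brinkman":
                aP = aP + k_M * phi_f * dx * dy
            else:
                vc = V[J, i]
                uc = 0.25 * (U[J - 1, i] + U[J - 1, i + 1] + U[J, i] + U[J, i + 1])
                speed = np.hypot(uc, vc)
                dirn = np.where(speed > 0, vc / np.maximum(speed, 1e-300), 0.0)
                bv -= k_M * phi_f * dx * dy * dirn
            co["v"] = dict(aE=aE, aW=aW, aN=aN, aS=aS, aP=aP, b=bv)
        return co

    def assemble(self, U, V, mu_c, phi_c, rho, k_M, sink_form="brinkman"):
        """Assemble the coupled sparse system for one Picard iteration."""
        g = self.grid
        dx, dy = g.dx, g.dy
        co = self.coefficients(U, V, mu_c, phi_c, rho, k_M, sink_form)
        rows, cols, data = [], [], []
        b = np.zeros(self.n)

        def add(r, c, d):
            r = np.atleast_1d(r)
            rows.append(r)
            cols.append(np.atleast_1d(c))
            data.append(np.broadcast_to(np.asarray(d, float), r.shape).copy())

        for block, nb_info, off in (("u", self.u_nb, 0), ("v", self.v_nb, self.nU)):
            if block not in co:
                continue
            c = co[block]
            nvar = self.nU if block == "u" else self.nV
            rr = np.arange(nvar) + off
            aP = c["aP"].copy()
            b[rr] += c["b"]
            for name in ("E", "W", "N", "S"):
                code, col, val, _ = nb_info[name]
                a = c["a" + name]
                unk = code == UNK
                add(rr[unk], col[unk] + off, -a[unk])
                alias = code == ALIAS
                aP[alias] -= a[alias]
                fixed = (code == DIR) | (code == WALLTAN)
                np.add.at(b, rr[fixed], a[fixed] * val[fixed])
            add(rr, rr, aP)
            # pressure gradient
            if block == "u":
                pL, pR = self.u_pL, self.u_pR
                known_L, known_R = self.u_pLval, self.u_pRval
                area = dy
            else:
                pL, pR = self.v_pB, self.v_pT
                known_L = np.zeros(nvar)
                known_R = np.zeros(nvar)
                area = dx
            # momentum row carries +area*p_R - area*p_L on the LHS; known
            # boundary pressures move to the RHS with opposite sign
            hasL = pL >= 0
            add(rr[hasL], self.nU + self.nV + pL[hasL], -area)
            np.add.at(b, rr[~hasL], area * known_L[~hasL])
            hasR = pR >= 0
            add(rr[hasR], self.nU + self.nV + pR[hasR], area)
            np.add.at(b, rr[~hasR], -area * known_R[~hasR])

        # ---- continuity ---------------------------------------------
        base = self.nU + self.nV
        rr = base + np.arange(self.nP)
        for f_idx, area, sign, off in (
            (self.c_uE, dy, +1.0, 0),
            (self.c_uW, dy, -1.0, 0),
            (self.c_vN, dx, +1.0, self.nU),
            (self.c_vS, dx, -1.0, self.nU),
        ):
            unk = f_idx >= 0
            add(rr[unk], f_idx[unk] + off, sign * area)
        # Dirichlet faces contribute known fluxes to the RHS
        jj, ii = self.c_jj, self.c_ii
        uW_dir = self.c_uW < 0
        b[rr[uW_dir]] += dy * self.Uval[jj[uW_dir], ii[uW_dir]]
        uE_dir = self.c_uE < 0
        b[rr[uE_dir]] -= dy * self.Uval[jj[uE_dir], ii[uE_dir] + 1]
        # Dirichlet v faces are always zero -> no RHS term

        if self.pin_pressure:
            # replace first continuity row with p = 0 (sealed domain gauge)
            pin_row = base
            rows_arr = np.concatenate([np.atleast_1d(r) for r in rows])
            cols_arr = np.concatenate([np.atleast_1d(cc) for cc in cols])
            data_arr = np.concatenate([np.atleast_1d(d) for d in data])
            mask = rows_arr != pin_row
            rows_arr, cols_arr, data_arr = (
                rows_arr[mask],
                cols_arr[mask],
                data_arr[mask],
            )
            rows_arr = np.append(rows_arr, pin_row)
            cols_arr = np.append(cols_arr, base)
            data_arr = np.append(data_arr, 1.0)
            b[pin_row] = 0.0
            A = sp.coo_matrix(
                (data_arr, (rows_arr, cols_arr)), shape=(self.n, self.n)
            ).tocsr()
            return A, b, co

        rows_arr = np.concatenate([np.atleast_1d(r) for r in rows])
        cols_arr = np.concatenate([np.atleast_1d(cc) for cc in cols])
        data_arr = np.concatenate([np.atleast_1d(d) for d in data])
        A = sp.coo_matrix(
            (data_arr, (rows_arr, cols_arr)), shape=(self.n, self.n)
        ).tocsr()
        return A, b, co

    # -----------------------------------------------------------------
    def pack(self, U, V, p):
        x = np.empty(self.n)
        x[: self.nU] = U[self.u_unk[:, 0], self.u_unk[:, 1]]
        x[self.nU : self.nU + self.nV] = V[self.v_unk[:, 0], self.v_unk[:, 1]]
        x[self.nU + self.nV :] = p[self.c_jj, self.c_ii]
        return x

    def unpack(self, x, U, V, p):
        U[self.u_unk[:, 0], self.u_unk[:, 1]] = x[: self.nU]
        V[self.v_unk[:, 0], self.v_unk[:, 1]] = x[self.nU : self.nU + self.nV]
        p[self.c_jj, self.c_ii] = x[self.nU + self.nV :]
        self.fill_faces(U, V)
        return U, V, p
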