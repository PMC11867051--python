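"""Glial ensheathment analytics on labeled voxel volumes.

Quantifies, on an integer label volume (lumen / endothelium / pericyte /
glia / neuron classes), the quantities measured on serial-EM
reconstructions of retinal capillaries:

* **surface coverage** — the fraction of the vessel surface covered by
  glia.  The vessel surface is the set of voxel faces between a vessel-wall
  voxel (endothelium or pericyte) and an exterior voxel (6-connectivity;
  lumen faces are interior and do not count).  Each face is classified by
  the role of its outside voxel, so glia faces + gap faces = total faces
  exactly.

* **gaps** — connected components of non-glia surface faces (faces are
  adjacent when they share a geometric voxel edge), each assigned to a
  vascular plexus (SVP / IVP / DVP) by binning its centroid depth.

* **contacts** — for each neuron process, maximal face-connected sets of
  surface faces whose outside voxels belong to that process; the contacted
  element is pericyte if any face's inside voxel is a pericyte, otherwise
  endothelium (pericytes lie external to endothelium, so a pericyte at the
  surface is the contacted element).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .synthetic import LABELS, LabeledVolume

#: default plexus depth bins (um below the retinal surface): the IVP and
#: DVP sit at roughly 50 and 90 um, so boundaries are drawn at 25 and 70
DEFAULT_PLEXUS_BINS_UM = (25.0, 70.0)


class VolumeValidationError(ValueError):
    pass


@dataclass
class SurfaceFaces:
    """Vessel-surface faces: voxel index, face axis/sign, and the labels on
    either side.  All arrays have one entry per face."""

    ijk: np.ndarray  # (N, 3) inside (wall) voxel index
    axis: np.ndarray  # (N,) face normal axis
    sign: np.ndarray  # (N,) +1 / -1
    inside_label: np.ndarray  # (N,)
    outside_label: np.ndarray  # (N,)
    voxel_size_um: tuple[float, float, float]

    def __len__(self) -> int:
        return len(self.axis)

    @property
    def areas_um2(self) -> np.ndarray:
        vs = self.voxel_size_um
        area_by_axis = np.array(
            [vs[1] * vs[2], vs[0] * vs[2], vs[0] * vs[1]]
        )
        return area_by_axis[self.axis]

    def centers_um(self, offset: tuple[float, float, float] = (0, 0, 0)) -> np.ndarray:
        """Physical face centers (voxel-center convention, +0.5*normal)."""
        vs = np.asarray(self.voxel_size_um)
        c = (self.ijk + 0.5).astype(float)
        c[np.arange(len(self)), self.axis] += 0.5 * self.sign
        return c * vs + np.asarray(offset)


@dataclass
class CoverageReport:
    total_surface_faces: int
    glia_faces: int
    coverage_fraction: float
    gaps: pd.DataFrame  # columns: gap_id, n_faces, area_um2, plexus, centroid depth
    contacts: pd.DataFrame  # columns: process_id, cls, target, n_faces
    contact_summary: pd.DataFrame  # counts and fractions by cls x target


def _neuron_labels(volume: LabeledVolume) -> set[int]:
    return {
        lab
        for lab, role in volume.label_map.items()
        if str(role).startswith("neuron")
    }


def extract_surface(volume: LabeledVolume) -> SurfaceFaces:
    """Enumerate vessel-surface faces and validate basic geometry."""
    volume.validate()
    labels = volume.labels
    vessel = (labels == LABELS["endothelium"]) | (labels == LABELS["pericyte"])
    lumen = labels == LABELS["lumen"]
    exterior = ~vessel & ~lumen

    # vessel wall must be a single connected component
    ncomp = ndimage.label(vessel)[1]
    if ncomp != 1:
        raise VolumeValidationError(
            f"vessel wall has {ncomp} connected components, expected 1"
        )
    # closed wall: lumen must never touch the exterior
    neuron = np.isin(labels, sorted(_neuron_labels(volume))) if _neuron_labels(
        volume
    ) else np.zeros_like(vessel)
    for axis in range(3):
        for sign in (1, -1):
            sl_a = [slice(None)] * 3
            sl_b = [slice(None)] * 3
            if sign == 1:
                sl_a[axis] = slice(None, -1)
                sl_b[axis] = slice(1, None)
            else:
                sl_a[axis] = slice(1, None)
                sl_b[axis] = slice(None, -1)
            if (lumen[tuple(sl_a)] & neuron[tuple(sl_b)]).any():
                raise VolumeValidationError(
                    "neuron voxel adjacent to lumen: impossible geometry"
                )
            if (lumen[tuple(sl_a)] & exterior[tuple(sl_b)]).any():
                raise VolumeValidationError("lumen touches exterior: wall not closed")

    ijk_list, ax_list, sg_list = [], [], []
    for axis in range(3):
        for sign in (1, -1):
            sl_in = [slice(None)] * 3
            sl_out = [slice(None)] * 3
            if sign == 1:
                sl_in[axis] = slice(None, -1)
                sl_out[axis] = slice(1, None)
            else:
                sl_in[axis] = slice(1, None)
                sl_out[axis] = slice(None, -1)
            face = vessel[tuple(sl_in)] & exterior[tuple(sl_out)]
            idx = np.argwhere(face)
            if sign == -1:
                idx = idx + np.eye(3, dtype=int)[axis]
            ijk_list.append(idx)
            ax_list.append(np.full(len(idx), axis))
            sg_list.append(np.full(len(idx), sign))
    ijk = np.concatenate(ijk_list)
    ax = np.concatenate(ax_list)
    sg = np.concatenate(sg_list)
    outside = ijk.copy()
    outside[np.arange(len(ax)), ax] += sg
    return SurfaceFaces(
        ijk=ijk,
        axis=ax,
        sign=sg,
        inside_label=labels[tuple(ijk.T)],
        outside_label=labels[tuple(outside.T)],
        voxel_size_um=volume.voxel_size_um,
    )


def surface_coverage(volume: LabeledVolume) -> tuple[SurfaceFaces, float]:
    """Glial coverage fraction of the vessel surface."""
    faces = extract_surface(volume)
    if len(faces) == 0:
        raise VolumeValidationError("vessel has no surface faces")
    glia = int((faces.outside_label == LABELS["glia"]).sum())
    return faces, glia / len(faces)


def _face_edge_keys(faces: SurfaceFaces, subset: np.ndarray) -> list[list[tuple]]:
    """For each selected face, the 4 canonical keys of its geometric edges.

    Corners live on a doubled integer grid; an edge is identified by its
    midpoint, which is unique per unit edge, so two faces share an edge iff
    they share a key.
    """
    keys = []
    for fi in np.nonzero(subset)[0]:
        i, j, k = faces.ijk[fi]
        a = faces.axis[fi]
        s = faces.sign[fi]
        center = np.array([2 * i + 1, 2 * j + 1, 2 * k + 1])
        center[a] += s
        b, c = [x for x in range(3) if x != a]
        f_keys = []
        for d, off in ((b, -1), (b, 1), (c, -1), (c, 1)):
            m = center.copy()
            m[d] += off
            f_keys.append(tuple(m))
        keys.append(f_keys)
    return keys


def _face_components(faces: SurfaceFaces, subset: np.ndarray) -> np.ndarray:
    """Label face-connected components within ``subset`` (shared-edge
    adjacency).  Returns per-selected-face component ids (0-based)."""
    sel = np.nonzero(subset)[0]
    n = len(sel)
    parent = np.arange(n)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    seen: dict[tuple, int] = {}
    for local, f_keys in enumerate(_face_edge_keys(faces, subset)):
        for key in f_keys:
            if key in seen:
                union(local, seen[key])
            else:
                seen[key] = local
    roots = np.array([find(i) for i in range(n)])
    _, comp = np.unique(roots, return_inverse=True)
    return comp


def find_gaps(
    faces: SurfaceFaces,
    volume: LabeledVolume,
    plexus_bins_um: tuple[float, float] = DEFAULT_PLEXUS_BINS_UM,
) -> pd.DataFrame:
    """Inventory gaps in the glial sheath.

    Gaps are connected components of non-glia surface faces.  Each gap's
    centroid depth (along the volume's depth axis) is binned into a plexus:
    SVP shallower than the first bin edge, IVP between the edges, DVP
    deeper than the second.
    """
    if plexus_bins_um is None or len(plexus_bins_um) != 2:
        raise ValueError("plexus_bins_um must supply two depth boundaries")
    not_glia = faces.outside_label != LABELS["glia"]
    cols = ["gap_id", "n_faces", "area_um2", "plexus", "centroid_depth_um"]
    if not not_glia.any():
        return pd.DataFrame(columns=cols)
    comp = _face_components(faces, not_glia)
    centers = faces.centers_um()[not_glia]
    depth = (
        centers[:, volume.depth_axis]
        - 0.5 * volume.voxel_size_um[volume.depth_axis]
        + volume.depth_offset_um
    )
    areas = faces.areas_um2[not_glia]
    lo, hi = plexus_bins_um
    rows = []
    for gid in range(comp.max() + 1):
        m = comp == gid
        d = float(depth[m].mean())
        plexus = "SVP" if d < lo else ("IVP" if d <= hi else "DVP")
        rows.append(
            {
                "gap_id": gid,
                "n_faces": int(m.sum()),
                "area_um2": float(areas[m].sum()),
                "plexus": plexus,
                "centroid_depth_um": d,
            }
        )
    return pd.DataFrame(rows, columns=cols)


def enumerate_contacts(
    volume: LabeledVolume, faces: SurfaceFaces | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate neuron contacts onto the vessel surface.

    A contact is a maximal face-connected set of surface faces whose
    outside voxels belong to a single neuron process.  Its target is
    pericyte if any inside voxel is pericyte, else endothelium.  Returns
    (contact table, summary by class x target with count fractions).
    """
    if faces is None:
        faces = extract_surface(volume)
    neuron_labels = sorted(_neuron_labels(volume))
    rows = []
    for lab in neuron_labels:
        sel = faces.outside_label == lab
        if not sel.any():
            continue
        comp = _face_components(faces, sel)
        inside = faces.inside_label[sel]
        for cid in range(comp.max() + 1):
            m = comp == cid
            target = (
                "pericyte"
                if (inside[m] == LABELS["pericyte"]).any()
                else "endothelium"
            )
            rows.append(
                {
                    "process_id": int(lab),
                    "cls": str(volume.label_map[lab]).replace("neuron_", ""),
                    "target": target,
                    "n_faces": int(m.sum()),
                }
            )
    contacts = pd.DataFrame(
        rows, columns=["process_id", "cls", "target", "n_faces"]
    )
    if len(contacts):
        summary = (
            contacts.groupby(["cls", "target"]).size().rename("n_contacts").reset_index()
        )
        summary["fraction"] = summary["n_contacts"] / summary["n_contacts"].sum()
    else:
        summary = pd.DataFrame(columns=["cls", "target", "n_contacts", "fraction"])
    return contacts, summary


def analyze_volume(
    volume: LabeledVolume,
    plexus_bins_um: tuple[float, float] = DEFAULT_PLEXUS_BINS_UM,
) -> CoverageReport:
    """Full ensheathment report: coverage, gap inventory, contact table."""
    faces, coverage = surface_coverage(volume)
    gaps = find_gaps(faces, volume, plexus_bins_um)
    contacts, summary = enumerate_contacts(volume, faces)
    glia_faces = int((faces.outside_label == LABELS["glia"]).sum())
    return CoverageReport(
        total_surface_faces=len(faces),
        glia_faces=glia_faces,
        coverage_fraction=coverage,
        gaps=gaps,
        contacts=contacts,
        contact_summary=summary,
    )
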