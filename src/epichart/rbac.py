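"""Role-based access control.

Permissions attach to roles and roles to users; a user's effective
grant set is the union over their roles. The policy is deny-by-default:
any (action, resource) pair not explicitly granted is denied. Access is
controlled at two levels — data operations (may this user finalize a
report?) and interface visibility (which dashboard/tracker surfaces
does this user see at all?).

The default grant table encodes the clinical division of labour:
technicians document recordings, fellows enter interpretations,
attendings finalize/transmit/bill, nurse navigators drive the journey
tracker, and admin holds every grant. Real installations edit the YAML
policy instead of code.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from epichart.errors import PermissionError_, PolicyError, ValidationError


class Role(enum.Enum):
    EEG_TECHNICIAN = "eeg_technician"
    CLINICAL_FELLOW = "clinical_fellow"
    ATTENDING_PHYSICIAN = "attending_physician"
    NURSE_NAVIGATOR = "nurse_navigator"
    ADMIN = "admin"


@dataclass(frozen=True)
class User:
    user_id: str
    display_name: str
    roles: frozenset[Role]

    def __post_init__(self) -> None:
        if not self.roles:
            raise ValidationError(f"user {self.user_id!r} must hold at least one role")

    def has_role(self, role: Role) -> bool:
        return role in self.roles


#: Action and resource vocabularies; names outside these are policy errors,
#: distinct from an ordinary deny.
ACTIONS = frozenset({
    "submit_technician_section", "submit_fellow_section", "submit_attending_section",
    "finalize", "transmit", "bill",
    "update_status", "comment",
    "view", "query", "export",
})
RESOURCE_TYPES = frozenset({
    "report", "tracker", "dashboard", "cohort", "schedule", "ontology",
})

#: Interface identifiers (the backend's notion of UI surfaces).
INTERFACES = frozenset({
    "reports_tab", "billing_tab", "statistics_tab", "schedule_tab",
    "tracker", "tracker_comment", "research_query", "data_entry",
})


@dataclass(frozen=True)
class Decision:
    """Outcome of a permission check; truthy iff allowed."""

    allowed: bool
    reason: str = ""

    def __bool__(self) -> bool:
        return self.allowed


@dataclass
class AccessPolicy:
    """Grant triples (role, action, resource_type) plus role → interface map."""

    grants: set[tuple[Role, str, str]] = field(default_factory=set)
    interface_map: dict[Role, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for role, action, resource in self.grants:
            if action not in ACTIONS or resource not in RESOURCE_TYPES:
                raise PolicyError(f"grant ({role}, {action!r}, {resource!r}) uses unknown names")
        for role, interfaces in self.interface_map.items():
            unknown = set(interfaces) - INTERFACES
            if unknown:
                raise PolicyError(f"interface map for {role} names unknown interfaces {unknown}")


def default_policy() -> AccessPolicy:
    grants: set[tuple[Role, str, str]] = set()

    def grant(role: Role, *pairs: tuple[str, str]) -> None:
        for action, resource in pairs:
            grants.add((role, action, resource))

    grant(Role.EEG_TECHNICIAN,
          ("submit_technician_section", "report"), ("view", "report"))
    grant(Role.CLINICAL_FELLOW,
          ("submit_fellow_section", "report"), ("view", "report"),
          ("view", "tracker"))
    grant(Role.ATTENDING_PHYSICIAN,
          ("submit_attending_section", "report"),
          ("finalize", "report"), ("transmit", "report"), ("bill", "report"),
          ("view", "report"), ("view", "dashboard"), ("view", "schedule"),
          ("view", "tracker"), ("query", "cohort"), ("export", "cohort"))
    grant(Role.NURSE_NAVIGATOR,
          ("update_status", "tracker"), ("comment", "tracker"),
          ("view", "tracker"), ("view", "report"))
    # admin: everything
    for action in ACTIONS:
        for resource in RESOURCE_TYPES:
            grants.add((Role.ADMIN, action, resource))

    interface_map = {
        Role.EEG_TECHNICIAN: frozenset({"data_entry", "reports_tab"}),
        Role.CLINICAL_FELLOW: frozenset({"data_entry", "reports_tab", "tracker"}),
        Role.ATTENDING_PHYSICIAN: frozenset({
            "data_entry", "reports_tab", "billing_tab", "statistics_tab",
            "schedule_tab", "tracker", "research_query"}),
        Role.NURSE_NAVIGATOR: frozenset({"tracker", "tracker_comment", "reports_tab"}),
        Role.ADMIN: frozenset(INTERFACES),
    }
    return AccessPolicy(grants=grants, interface_map=interface_map)


def check_permission(policy: AccessPolicy, user: User, action: str, resource_type: str) -> Decision:
    """Allow iff any of the user's roles grants (action, resource_type).

    Unknown action/resource names raise :class:`PolicyError` — a
    misconfigured caller, not a denied user.
    """
    if action not in ACTIONS:
        raise PolicyError(f"unknown action {action!r}")
    if resource_type not in RESOURCE_TYPES:
        raise PolicyError(f"unknown resource type {resource_type!r}")
    for role in user.roles:
        if (role, action, resource_type) in policy.grants:
            return Decision(True, f"granted via role {role.value}")
    # closest-missing-grant hint: which roles *do* hold this action, if any
    holders = sorted({r.value for (r, a, rt) in policy.grants
                      if a == action and rt == resource_type})
    hint = f"; granted to roles {holders}" if holders else "; granted to no role"
    return Decision(False, f"no role of user {user.user_id!r} grants "
                           f"({action}, {resource_type}){hint}")


def require(policy: AccessPolicy, user: User, action: str, resource_type: str) -> None:
    """Raise :class:`PermissionError_` unless the check allows."""
    decision = check_permission(policy, user, action, resource_type)
    if not decision:
        raise PermissionError_(decision.reason)


def visible_interfaces(policy: AccessPolicy, user: User) -> frozenset[str]:
    """Union of interface visibility over the user's roles."""
    out: set[str] = set()
    for role in user.roles:
        out |= policy.interface_map.get(role, frozenset())
    return frozenset(out)


# --- YAML round-trip ---------------------------------------------------


def policy_to_dict(policy: AccessPolicy) -> dict:
    return {
        "grants": sorted(
            ({"role": r.value, "action": a, "resource": rt}
             for r, a, rt in policy.grants),
            key=lambda d: (d["role"], d["action"], d["resource"])),
        "interfaces": {r.value: sorted(v) for r, v in sorted(
            policy.interface_map.items(), key=lambda kv: kv[0].value)},
    }


def save_policy(policy: AccessPolicy, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(policy_to_dict(policy), sort_keys=False))


def load_policy(path: str | Path) -> AccessPolicy:
    """Load a policy from YAML written by :func:`save_policy` (or by hand)."""
    data = yaml.safe_load(Path(path).read_text())
    try:
        grants = {(Role(g["role"]), g["action"], g["resource"]) for g in data["grants"]}
        interface_map = {Role(name): frozenset(ifaces)
                         for name, ifaces in data.get("interfaces", {}).items()}
    except (KeyError, TypeError, ValueError) as exc:
        raise PolicyError(f"malformed policy file {path}: {exc}") from None
    return AccessPolicy(grants=grants, interface_map=interface_map)
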