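{
  "description": "Topic clusters inferred on the full social work note corpus (17 topics, top-10 words each); used as worked-example input for the labeling heuristic.",
  "topics": {
    "1": ["goal", "anxiety", "problem", "term", "depression", "mood", "therapy", "symptom", "long", "treatment"],
    "2": ["recommendation", "wife", "education", "treatment", "patient", "form", "appearance", "ongoing", "advocate", "trauma"],
    "3": ["hospital", "self", "day", "pain", "other", "connection", "recent", "feeling", "side", "number"],
    "4": ["mother", "father", "family", "room", "information", "nurse", "source", "concrete", "control", "instruction"],
    "5": ["session", "consultation", "telehealth", "location", "time", "tool", "objective", "parking", "other", "treatment"],
    "6": ["parent", "family", "school", "child", "sister", "support", "place", "year", "well", "initial"],
    "7": ["group", "intervention", "patient", "discussion", "response", "time", "summary", "progress", "participant", "skill"],
    "8": ["risk", "chronic", "thought", "normal", "imminent", "status", "testing", "intervention", "speech", "suicide"],
    "9": ["client", "health", "service", "caregiver", "mental", "therapist", "therapy", "behavioral", "individual", "group"],
    "10": ["well", "when", "time", "week", "also", "able", "state", "more", "friend", "very"],
    "11": ["social", "service", "support", "family", "assessment", "medical", "time", "note", "concern", "ongoing"],
    "12": ["care", "home", "plan", "phone", "contact", "work", "information", "resource", "call", "support"],
    "13": ["time", "clinician", "name", "date", "code", "behavior", "risk", "number", "plan", "provider"],
    "14": ["history", "child", "other", "factor", "current", "none", "substance", "abuse", "psychiatric", "year"],
    "15": ["donor", "donation", "potential", "employment", "understanding", "risk", "decision", "independent", "process", "care"],
    "16": ["night", "morning", "hour", "sleep", "house", "already", "less", "past", "aggressive", "evening"],
    "17": ["transplant", "medication", "post", "support", "health", "insurance", "husband", "psychosocial", "message", "history"]
  }
}
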