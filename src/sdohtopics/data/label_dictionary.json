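{
  "Mental health": ["mental", "depression", "anxiety", "mood", "psychological", "physical", "cognitive", "emotional", "mind", "psychiatric"],
  "Family": ["family", "parent", "father", "mother", "child", "children", "sister", "parents", "relatives", "clan", "childhood", "friends"],
  "Consultation/appointment": ["appointment", "consultation", "consult", "questionnaire", "question", "advice", "biographical", "wikipedia", "relevant", "questions", "know", "documentation"],
  "Group session": ["group", "intervention", "session", "interpers", "community", "class", "organization", "together", "part"],
  "Risk of death": ["suicide", "suicidal", "risk", "crisis", "homicide", "murder", "commit", "bombing", "murdered", "murders", "bomber", "killing", "convicted", "victims"],
  "Clinician/hospital/medication": ["patient", "medication", "hospital", "medical", "clinic", "clinician", "treatment", "therapy", "surgery", "symptoms", "patients", "drugs", "diagnosis", "treatments", "prescribed"],
  "Living condition/lifestyle": ["shelter", "housing", "house", "living", "sleep", "bedtime", "building", "buildings", "urban", "employment", "suburban", "campus", "acres"],
  "Social support": ["social", "service", "support", "referral", "recommendation", "recommend", "worker", "resource", "supports", "provide", "supporting", "supported", "allow", "providing", "assistance", "benefit", "help"],
  "TelephoneEcounter/online communication": ["telehealth", "phone", "call", "video", "telephone", "mobile", "wireless", "gsm", "cellular", "dial", "email", "calling", "networks", "calls", "messages", "telephones", "internet"],
  "Abuse history": ["abuse", "history", "addiction", "alcohol", "drugs", "allegations", "victim", "violence", "sexual", "rape", "dependence"],
  "Insurance/income": ["insurance", "income", "coverage", "financial", "contracts", "banking", "finance", "liability", "private", "pay"]
}
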