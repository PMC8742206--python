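{"anchored_text": "chest x - ray showed no new lesion , no [A] pleural effusion [/A] or pneumothorax and history of smoking .", "concept_text": "pleural effusion", "cui": "C0032227", "doc_id": "hc-negation-1", "label": "negative"}
{"anchored_text": "chest x - ray showed no new lesion , no pleural effusion or [A] pneumothorax [/A] and history of smoking .", "concept_text": "pneumothorax", "cui": "C0032326", "doc_id": "hc-negation-1", "label": "negative"}
{"anchored_text": "chest x - ray showed no new [A] lesion [/A] , no pleural effusion or pneumothorax and history of smoking .", "concept_text": "lesion", "cui": "C0221198", "doc_id": "hc-negation-1", "label": "negative"}
{"anchored_text": "admitted with right scaptula / [A] back pain [/A] , no chest pain or dyspnea .", "concept_text": "back pain", "cui": "C0004604", "doc_id": "hc-negation-2", "label": "positive"}
{"anchored_text": "admitted with right scaptula / back pain , no [A] chest pain [/A] or dyspnea .", "concept_text": "chest pain", "cui": "C0008031", "doc_id": "hc-negation-2", "label": "negative"}
{"anchored_text": "admitted with right scaptula / back pain , no chest pain or [A] dyspnea [/A] .", "concept_text": "dyspnea", "cui": "C0013404", "doc_id": "hc-negation-2", "label": "negative"}
{"anchored_text": "patient reported [A] decreased mobility [/A] following treatment .", "concept_text": "decreased mobility", "cui": "C0587597", "doc_id": "hc-polarity-pos", "label": "positive"}
{"anchored_text": "patient reported decreased [A] pain [/A] following treatment .", "concept_text": "pain", "cui": "C0030193", "doc_id": "hc-polarity-neg", "label": "negative"}
{"anchored_text": "admitted to hospital with lower [A] respiratory tract infection [/A] . not commenced chemotherapy related infection .", "concept_text": "respiratory tract infection", "cui": "C0035243", "doc_id": "hc-multi-context", "label": "positive"}
{"anchored_text": "admitted to hospital with lower respiratory tract infection . not commenced chemotherapy related [A] infection [/A] .", "concept_text": "infection", "cui": "C3714514", "doc_id": "hc-multi-context", "label": "positive"}
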