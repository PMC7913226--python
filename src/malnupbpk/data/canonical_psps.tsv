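component	mild	intermediate	severe
bone	0.947	0.913	0.869
brain	0.918	0.865	0.797
fat	0.817	0.822	0.624
lean_group	0.936	0.894	0.84
heart	0.902	0.839	0.758
kidney	0.874	0.792	0.686
liver	0.872	0.789	0.682
muscle	0.893	0.771	0.715
pancreas	0.936	0.894	0.84
skin	0.954	0.922	0.879
spleen	0.844	0.743	0.612
blood_arterial	1.03	0.992	0.833
blood_venous	1.02	0.979	0.822
blood_portal	1.02	0.982	0.825
plasma_proteins	0.894	0.706	0.494
hematocrit	0.945	0.791	0.681
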