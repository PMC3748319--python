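family	1-I	1-II	1-III	1-IV	0	2-I	2-II	2-III	2-IV	2-V	2-VI
Acanthaceae	+	+	+								
Apocynaceae	+			+	+	+					
Asteraceae								+	+		
Bignoniaceae	+	+									
Boraginaceae						+		+			
Campanulaceae				+							
Convolvulaceae				+							
Cornaceae	+										
Eucommiaceae	+										
Gentianaceae					+	+				+	
Gesneriaceae	+										
Griseliniaceae	+										
Hydrangeaceae	+										
Lamiaceae	+	+	+								
Oleaceae	+										
Orobanchaceae	+	+									+
Pawlowniaceae	+										
Phrymaceae		+									
Plantaginaceae	+	+	+		+	+	+	+	+		
Polemoniaceae						+	+				
Rubiaceae	+	+			+			+			
Scrophulariaceae	+	+	+								
Solanaceae						+		+	+		
Verbenaceae	+	+									
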